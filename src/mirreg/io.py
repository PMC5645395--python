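"""Readers, writers and run configuration.

All tabular formats are plain TSV.  Feature-by-sample tables (expression,
CNV, methylation) have a header row of sample ids and feature ids in the
first column.  Every table the pipeline writes starts with a commented
header block (lines beginning ``#``) recording the tool version, the seed
and a digest of the run configuration, so any output file can be traced
back to the exact run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("mirreg")

STAGES = ("I", "II", "III", "IV")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Tunable thresholds, grids and sampling parameters for a full run.

    Defaults follow the method's operating points: per-site Bonferroni
    alpha 0.05, differential-expression fold change 2 with BH alpha 0.05,
    module q-value cutoff 0.05, 5-fold / 2-round hierarchical sampling
    (25 subsets of 64% of samples), and module sizes k = 1..5.
    """

    site_alpha: float = 0.05
    de_fold_change: float = 2.0
    de_alpha: float = 0.05
    expression_floor: float = 0.0  # median tumor expression must exceed this
    pseudocount: float = 0.5
    module_q: float = 0.05
    enrichment_alpha: float = 0.05
    involvement_alpha: float = 0.05
    # penalty grids, as fractions of the data-derived maximal penalty
    w_grid: tuple[float, ...] = (0.5, 0.2, 0.1, 0.05)
    lambda_grid: tuple[float, ...] = (0.3, 0.1)
    folds: int = 5
    rounds: int = 2
    stability_repetitions: int = 100
    consistency_fraction: float = 0.5
    k_min: int = 1
    k_max: int = 5
    pathway_mirna_cap: int = 30
    candidate_cap: int | None = None
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("site_alpha", "de_alpha", "module_q", "enrichment_alpha",
                     "involvement_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("need 1 <= k_min <= k_max")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (json.loads(text) if path.suffix == ".json"
                else yaml.safe_load(text)) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        for k in ("w_grid", "lambda_grid"):
            if k in data:
                data[k] = tuple(data[k])
        return cls(**data)

    def digest(self) -> str:
        payload = asdict(self)
        payload.pop("paths", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# feature x sample tables
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, *, nonnegative: bool = True) -> pd.DataFrame:
    """Read a feature-by-sample TSV into a validated DataFrame.

    The first column holds feature ids (genes or miRNAs), the header row
    holds sample ids.  Values must be finite reals, non-negative unless
    ``nonnegative=False``; duplicate feature or sample ids are rejected.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    dup_rows = df.index[df.index.duplicated()].unique().tolist()
    if dup_rows:
        raise FormatError(f"{path}: duplicated feature id(s) {dup_rows}")
    dup_cols = df.columns[df.columns.duplicated()].unique().tolist()
    if dup_cols:
        raise FormatError(f"{path}: duplicated sample id(s) {dup_cols}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        nonnum = bad.isna() & df[col].notna()
        if nonnum.any():
            row = df.index[nonnum.argmax()]
            raise FormatError(
                f"{path}: non-numeric value at feature {row!r}, sample {col!r}")
        df[col] = bad
    values = df.to_numpy(dtype=float)
    import numpy as np
    if not np.isfinite(values).all():
        raise FormatError(f"{path}: non-finite values present")
    if nonnegative and (values < 0).any():
        raise FormatError(f"{path}: negative expression values present")
    logger.info("read %s: %d features x %d samples", path.name, *df.shape)
    return df


def read_signed_table(path: str | Path) -> pd.DataFrame:
    """Read a feature-by-sample TSV that may contain negative values.

    CNV log-ratios and methylation beta values are signed / bounded rather
    than non-negative counts; the format otherwise matches
    :func:`read_expression`.
    """
    return read_expression(path, nonnegative=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the sample sheet (sample_id, cancer_type, stage, status).

    Tumor samples must carry a stage in {I, II, III, IV}; every cancer type
    must have at least one normal sample.  Shared normals across cancer
    subtypes are expressed by listing the same normal sample id under each
    cancer, so (sample_id, cancer_type) is the unique key, not sample_id.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "cancer_type", "stage", "status"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df.duplicated(["sample_id", "cancer_type"]).any():
        dup = df.loc[df.duplicated(["sample_id", "cancer_type"]), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicated (sample, cancer) entry {dup!r}")
    bad_status = set(df["status"]) - {"tumor", "normal"}
    if bad_status:
        raise FormatError(f"{path}: invalid status values {sorted(bad_status)}")
    tumors = df[df["status"] == "tumor"]
    bad_stage = ~tumors["stage"].isin(STAGES)
    if bad_stage.any():
        sid = tumors.loc[bad_stage, "sample_id"].iloc[0]
        raise FormatError(f"{path}: tumor sample {sid!r} lacks a valid stage")
    for cancer, grp in df.groupby("cancer_type"):
        if not (grp["status"] == "normal").any():
            raise FormatError(f"{path}: cancer {cancer!r} has no normal sample")
    return df


def conditions_from_sheet(sheet: pd.DataFrame) -> list[tuple[str, str]]:
    """Enumerate the (cancer_type, stage) conditions present in a sheet.

    Only conditions with at least one tumor sample are returned, ordered
    by cancer then stage.
    """
    tumors = sheet[sheet["status"] == "tumor"]
    seen = {(c, s) for c, s in zip(tumors["cancer_type"], tumors["stage"])}
    order = {s: i for i, s in enumerate(STAGES)}
    return sorted(seen, key=lambda cs: (cs[0], order[cs[1]]))


def condition_samples(sheet: pd.DataFrame, cancer: str, stage: str
                      ) -> tuple[list[str], list[str]]:
    """Tumor sample ids of one condition plus that cancer's normal controls."""
    tum = sheet[(sheet["cancer_type"] == cancer) & (sheet["stage"] == stage)
                & (sheet["status"] == "tumor")]["sample_id"].tolist()
    nor = sheet[(sheet["cancer_type"] == cancer)
                & (sheet["status"] == "normal")]["sample_id"].tolist()
    return tum, nor


# ---------------------------------------------------------------------------
# GMT pathway collections
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Parse a GMT file into ``{pathway_name: gene set}``.

    Standard GMT: one pathway per line, tab-separated fields
    ``name<TAB>description<TAB>gene1<TAB>gene2...``.  Duplicate member genes
    collapse to a set; an empty file yields an empty collection with a
    warning.
    """
    path = Path(path)
    pathways: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{ln}: GMT line needs >= 3 fields, got {len(fields)}")
            name = fields[0]
            if name in pathways:
                raise FormatError(f"{path}:{ln}: duplicated pathway {name!r}")
            pathways[name] = frozenset(g for g in fields[2:] if g)
    if not pathways:
        logger.warning("read_gmt(%s): empty pathway collection", path)
    return pathways


def write_gmt(pathways: Mapping[str, frozenset[str] | set[str]],
              path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(pathways):
            genes = "\t".join(sorted(pathways[name]))
            fh.write(f"{name}\tna\t{genes}\n")


def validate_mirna_ids(fasta_path: str | Path,
                       mirna_ids: Sequence[str]) -> list[str]:
    """Check miRNA ids against a mature-miRNA FASTA; returns unknown ids.

    The FASTA is used for id validation only — sequences are ignored.
    """
    from Bio import SeqIO

    known = {rec.id for rec in SeqIO.parse(str(fasta_path), "fasta")}
    unknown = sorted(set(mirna_ids) - known)
    if unknown:
        logger.warning("%d miRNA id(s) absent from %s (e.g. %s)",
                       len(unknown), fasta_path, unknown[:3])
    return unknown


# ---------------------------------------------------------------------------
# generic TSV with provenance header
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path, *,
                config: RunConfig | None = None,
                index: bool = False,
                float_format: str = "%.10g") -> None:
    """Write a TSV with a ``#`` provenance header (version, seed, digest)."""
    from mirreg import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# mirreg {__version__}\n")
        if config is not None:
            fh.write(f"# seed {config.seed}\n")
            fh.write(f"# config {config.digest()}\n")
        df.to_csv(fh, sep="\t", index=index, float_format=float_format)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`, skipping ``#`` lines."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_binding_sites(path: str | Path) -> pd.DataFrame:
    """Read the binding-site evidence TSV.

    Columns: mirna_id, mrna_id, site_id, tx_id, start, end (0-based
    half-open transcript coordinates), chimeric_count (>= 0), mfe (<= 0,
    kcal/mol).  (mirna_id, mrna_id, site_id) must be unique.
    """
    df = read_table(path)
    required = {"mirna_id", "mrna_id", "site_id", "chimeric_count", "mfe"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    key = ["mirna_id", "mrna_id", "site_id"]
    if df.duplicated(key).any():
        dup = df.loc[df.duplicated(key), key].iloc[0].tolist()
        raise FormatError(f"{path}: duplicated site {dup}")
    if (df["chimeric_count"] < 0).any():
        raise FormatError(f"{path}: negative chimeric_count")
    if (df["mfe"] > 0).any():
        raise FormatError(f"{path}: positive MFE (must be <= 0 kcal/mol)")
    return df


def read_single_reads(path: str | Path, id_col: str) -> pd.Series:
    """Read a single-read count TSV keyed by miRNA or mRNA id."""
    df = read_table(path)
    if id_col not in df.columns or "single_count" not in df.columns:
        raise FormatError(f"{path}: need columns {id_col!r} and 'single_count'")
    if df.duplicated(id_col).any():
        raise FormatError(f"{path}: duplicated {id_col}")
    s = df.set_index(id_col)["single_count"]
    if (s < 0).any():
        raise FormatError(f"{path}: negative single-read count")
    return s


def read_tf_sites(path: str | Path) -> pd.DataFrame:
    """Read the TF binding-site TSV (tf_id, gene_id, site_id, tss_distance)."""
    df = read_table(path)
    required = {"tf_id", "gene_id", "site_id", "tss_distance"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if (df["tss_distance"] < 0).any():
        raise FormatError(f"{path}: negative tss_distance")
    return df


def read_mutations(path: str | Path) -> pd.DataFrame:
    """Read somatic-mutation flags per binding site: (site_id, cancer_type, stage)."""
    df = read_table(path, dtype=str)
    required = {"site_id", "cancer_type", "stage"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df
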