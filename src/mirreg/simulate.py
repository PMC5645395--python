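"""Ground-truth-labeled synthetic input bundles.

Generates every external input the pipeline consumes — binding-site
evidence with read tallies, TF binding sites, expression/CNV/methylation
tables with a sample sheet, somatic-mutation flags and a GMT pathway
collection — from a planted regulatory network, so each stage and the full
pipeline can be validated against known truth without any download.

The generative model mirrors the pipeline's own assumptions: per tumor
sample, a regulated gene's log2 change is a linear combination of its
regulators' log2 changes (miRNA effects negative — repression — TF effects
either sign) plus CNV and methylation background plus Gaussian noise.
Chimeric and single read counts are negative-binomial (overdispersed, as
chimeric-read libraries are); binding-site free energies are uniform on
the empirical range [-31.2, -2.9] kcal/mol.  A k-miRNA module is planted
by making its member miRNAs co-regulate a shared set of genes, co-assigned
to the module's pathways, in a chosen subset of conditions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mirreg import io as mio

STAGES = ("I", "II", "III")


@dataclass
class ModuleSpec:
    """A planted k-miRNA module: size, supporting conditions, pathways."""

    k: int = 4
    n_conditions: int = 3
    n_pathways: int = 2
    n_target_genes: int = 12


@dataclass
class GroundTruthNetwork:
    """Planted regulatory truth: id universes, per-condition edges, module."""

    gene_ids: list[str]
    mirna_ids: list[str]
    tf_ids: list[str]
    conditions: list[tuple[str, str]]
    edges: pd.DataFrame          # cancer_type, stage, gene_id, regulator_id, kind, effect
    mirna_shift: dict[str, float]  # per-miRNA tumor log2 shift (DE direction)
    tf_shift: dict[str, float]
    module_mirnas: list[str] = field(default_factory=list)
    module_genes: list[str] = field(default_factory=list)
    module_pathways: list[str] = field(default_factory=list)
    module_conditions: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0

    def true_pairs(self) -> pd.DataFrame:
        """Unique (miRNA, gene) pairs with any true edge in any condition."""
        mi = self.edges[self.edges["kind"] == "miRNA"]
        return (mi[["regulator_id", "gene_id"]].drop_duplicates()
                .rename(columns={"regulator_id": "mirna_id",
                                 "gene_id": "mrna_id"})
                .reset_index(drop=True))


def generate_truth(n_genes: int = 200, n_mirnas: int = 30, n_tfs: int = 10,
                   n_conditions: int = 6, regulators_per_gene: int = 3,
                   regulated_genes_per_condition: int = 40,
                   module_spec: ModuleSpec | None = None,
                   bystander_fraction: float = 0.3,
                   seed: int = 1) -> GroundTruthNetwork:
    """Plant a regulatory network with one k-miRNA module.

    Each condition gets ``regulated_genes_per_condition`` regulated genes,
    each with ``regulators_per_gene`` true regulators (mostly miRNAs, one
    TF); true-regulator miRNAs are upregulated in tumors (log2 shift 1.5)
    so their repressive effects reinforce rather than cancel, keeping
    regulated genes differentially expressed.  A ``bystander_fraction`` of
    the remaining miRNAs is also made DE without any regulatory effect —
    true-negative candidates for the selection step.
    """
    if min(n_genes, n_mirnas, n_tfs, n_conditions) < 1:
        raise ValueError("all entity counts must be >= 1")
    module_spec = module_spec or ModuleSpec()
    if module_spec.k > n_mirnas:
        raise ValueError("module size exceeds the miRNA universe")
    if module_spec.n_conditions > n_conditions:
        raise ValueError("module supported in more conditions than exist")
    if module_spec.n_target_genes > n_genes:
        raise ValueError("module targets exceed the gene universe")
    rng = np.random.default_rng(seed)

    gene_ids = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    mirna_ids = [f"miR-{i:03d}" for i in range(1, n_mirnas + 1)]
    tf_ids = [f"TF{i:02d}" for i in range(1, n_tfs + 1)]
    n_cancers = max(1, (n_conditions + len(STAGES) - 1) // len(STAGES))
    conditions = []
    for ci in range(n_cancers):
        for s in STAGES:
            if len(conditions) < n_conditions:
                conditions.append((f"CAN{ci + 1}", s))

    module_mirnas = list(rng.choice(mirna_ids, module_spec.k, replace=False))
    module_genes = list(rng.choice(gene_ids, module_spec.n_target_genes,
                                   replace=False))
    mc_idx = rng.choice(n_conditions, module_spec.n_conditions, replace=False)
    module_conditions = [conditions[i] for i in sorted(mc_idx)]
    module_pathways = [f"PW{i:03d}" for i in range(1, module_spec.n_pathways + 1)]

    # DE shifts: true-regulator and bystander miRNAs are shifted; the rest flat
    mirna_shift = {m: 0.0 for m in mirna_ids}
    tf_shift = {t: float(rng.uniform(1.2, 1.8) * rng.choice([-1, 1]))
                for t in tf_ids}

    rows = []
    for cancer, stage in conditions:
        regulated = list(rng.choice(gene_ids, regulated_genes_per_condition,
                                    replace=False))
        in_module = (cancer, stage) in module_conditions
        if in_module:
            regulated = list(dict.fromkeys(module_genes + regulated))
        for gene in regulated:
            n_mir = max(1, regulators_per_gene - 1)
            mirs = list(rng.choice(mirna_ids, n_mir, replace=False))
            if in_module and gene in module_genes:
                # module miRNAs dominate the module genes' regulation
                take = min(len(module_mirnas), regulators_per_gene)
                mirs = list(rng.choice(module_mirnas, take, replace=False))
            tfs = list(rng.choice(tf_ids, regulators_per_gene - len(mirs),
                                  replace=False)) \
                if regulators_per_gene > len(mirs) else []
            for m in mirs:
                rows.append((cancer, stage, gene, m, "miRNA",
                             -float(rng.uniform(0.5, 1.5))))
                if mirna_shift[m] == 0.0:
                    mirna_shift[m] = float(rng.uniform(1.3, 1.8))
            for t in tfs:
                # effect sign opposite the TF's own shift: the TF term then
                # pushes the gene the same way as the miRNA repression, so
                # planted genes stay detectably DE (no self-cancellation)
                rows.append((cancer, stage, gene, t, "TF",
                             -float(rng.uniform(0.5, 1.5))
                             * float(np.sign(tf_shift[t]))))
    edges = pd.DataFrame(rows, columns=["cancer_type", "stage", "gene_id",
                                        "regulator_id", "kind", "effect"])
    edges = edges.drop_duplicates(
        ["cancer_type", "stage", "gene_id", "regulator_id"])

    flat = [m for m in mirna_ids if mirna_shift[m] == 0.0]
    n_bystanders = int(round(bystander_fraction * len(flat)))
    for m in rng.choice(flat, n_bystanders, replace=False) if n_bystanders else []:
        mirna_shift[m] = float(rng.uniform(1.3, 1.8) * rng.choice([-1, 1]))

    return GroundTruthNetwork(
        gene_ids=gene_ids, mirna_ids=mirna_ids, tf_ids=tf_ids,
        conditions=conditions, edges=edges, mirna_shift=mirna_shift,
        tf_shift=tf_shift, module_mirnas=sorted(module_mirnas),
        module_genes=module_genes, module_pathways=module_pathways,
        module_conditions=module_conditions, seed=seed)


def _nbinom(rng, mean, size_param, n):
    """Negative binomial draws parameterized by mean and dispersion size."""
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, n)


def generate_binding_evidence(truth: GroundTruthNetwork, depth: float = 1.0,
                              decoy_pairs: int = 500,
                              dispersion: float = 0.5,
                              seed: int = 2) -> dict[str, pd.DataFrame | pd.Series]:
    """Chimeric-read binding evidence plus single-read tallies.

    True miRNA-gene pairs get 1-3 sites with high-mean negative-binomial
    chimeric counts; ``decoy_pairs`` random non-true pairs get low-mean
    counts.  Single reads dominate each molecule's total, as in real
    chimeric-read libraries, which is what makes true sites detectable
    against the null.  ``depth`` scales every mean jointly.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    true = truth.true_pairs()
    true_set = set(zip(true["mirna_id"], true["mrna_id"]))
    n_possible = len(truth.mirna_ids) * len(truth.gene_ids) - len(true_set)
    decoy_pairs = min(decoy_pairs, n_possible)
    decoys: set[tuple[str, str]] = set()
    while len(decoys) < decoy_pairs:
        m = truth.mirna_ids[rng.integers(len(truth.mirna_ids))]
        g = truth.gene_ids[rng.integers(len(truth.gene_ids))]
        if (m, g) not in true_set:
            decoys.add((m, g))

    rows = []
    sid = 0
    for (m, g), is_true in [*((p, True) for p in sorted(true_set)),
                            *((p, False) for p in sorted(decoys))]:
        n_sites = int(rng.integers(1, 4)) if is_true else 1
        mean = (30.0 if is_true else 0.6) * depth
        counts = _nbinom(rng, mean, dispersion, n_sites) if depth > 0 \
            else np.zeros(n_sites, dtype=int)
        for k in range(n_sites):
            start = int(rng.integers(0, 2000))
            sid += 1
            rows.append({
                "mirna_id": m, "mrna_id": g, "site_id": f"S{sid:06d}",
                "tx_id": g, "start": start, "end": start + 22,
                "chimeric_count": int(counts[k]),
                "mfe": float(rng.uniform(-31.2, -2.9)),
                "is_true": is_true,
            })
    sites = pd.DataFrame(rows)
    # depth scales the chimeric library; single reads stay present even at
    # depth 0 (the degenerate "no chimera captured" case)
    single_scale = depth if depth > 0 else 1.0
    mirna_singles = pd.Series(
        _nbinom(rng, 20000.0 * single_scale, 5.0, len(truth.mirna_ids)),
        index=pd.Index(truth.mirna_ids, name="mirna_id"), name="single_count")
    mrna_singles = pd.Series(
        _nbinom(rng, 5000.0 * single_scale, 5.0, len(truth.gene_ids)),
        index=pd.Index(truth.gene_ids, name="mrna_id"), name="single_count")
    return {"sites": sites, "mirna_singles": mirna_singles,
            "mrna_singles": mrna_singles}


def generate_tf_sites(truth: GroundTruthNetwork, decoy_sites: int = 100,
                      seed: int = 3) -> pd.DataFrame:
    """TF binding sites: 1-2 per true TF-gene edge plus random decoys."""
    rng = np.random.default_rng(seed)
    tf_edges = truth.edges[truth.edges["kind"] == "TF"]
    pairs = set(zip(tf_edges["regulator_id"], tf_edges["gene_id"]))
    rows = []
    sid = 0
    for t, g in sorted(pairs):
        for _ in range(int(rng.integers(1, 3))):
            sid += 1
            rows.append({"tf_id": t, "gene_id": g, "site_id": f"T{sid:05d}",
                         "tss_distance": int(rng.integers(0, 50000))})
    for _ in range(decoy_sites):
        t = truth.tf_ids[rng.integers(len(truth.tf_ids))]
        g = truth.gene_ids[rng.integers(len(truth.gene_ids))]
        sid += 1
        rows.append({"tf_id": t, "gene_id": g, "site_id": f"T{sid:05d}",
                     "tss_distance": int(rng.integers(0, 80000))})
    return pd.DataFrame(rows)


def generate_expression(truth: GroundTruthNetwork,
                        samples_per_condition: int = 60,
                        normals_per_cancer: int = 30,
                        noise_sd: float = 0.5,
                        seed: int = 4) -> dict[str, pd.DataFrame]:
    """Expression/CNV/methylation tables plus the sample sheet.

    Normals are log-normal around a per-feature baseline.  Tumor log2
    changes follow the linear model: regulator shifts (the planted DE
    direction plus per-sample noise) propagate to regulated genes through
    the signed effects, on top of CNV (dosage, coefficient +1) and
    methylation (repressive, coefficient -1) background and N(0, noise_sd)
    residual noise.
    """
    if samples_per_condition < 10:
        raise ValueError("need >= 10 samples per condition")
    rng = np.random.default_rng(seed)
    genes, mirnas = truth.gene_ids, truth.mirna_ids
    all_gene_feats = genes + truth.tf_ids  # TFs are genes: one table
    base_gene = pd.Series(np.exp(rng.normal(np.log(100), 0.4,
                                            len(all_gene_feats))),
                          index=all_gene_feats)
    base_mir = pd.Series(np.exp(rng.normal(np.log(200), 0.4, len(mirnas))),
                         index=mirnas)

    sheet_rows = []
    gene_cols: dict[str, np.ndarray] = {}
    mir_cols: dict[str, np.ndarray] = {}
    cnv_cols: dict[str, np.ndarray] = {}
    meth_cols: dict[str, np.ndarray] = {}
    cancers = sorted({c for c, _ in truth.conditions})

    # normals per cancer (shared across that cancer's stages)
    for cancer in cancers:
        for i in range(normals_per_cancer):
            sid = f"{cancer}_N{i:03d}"
            sheet_rows.append((sid, cancer, "NA", "normal"))
            gene_cols[sid] = base_gene.to_numpy() \
                * 2.0 ** rng.normal(0, 0.25, len(all_gene_feats))
            mir_cols[sid] = base_mir.to_numpy() \
                * 2.0 ** rng.normal(0, 0.25, len(mirnas))
            cnv_cols[sid] = 2.0 * 2.0 ** rng.normal(0, 0.05, len(genes))
            meth_cols[sid] = np.clip(rng.normal(0.5, 0.03, len(genes)), 0, 1)

    gene_pos = {g: i for i, g in enumerate(all_gene_feats)}
    mir_pos = {m: i for i, m in enumerate(mirnas)}
    for cancer, stage in truth.conditions:
        cond_edges = truth.edges[(truth.edges["cancer_type"] == cancer)
                                 & (truth.edges["stage"] == stage)]
        by_gene = {g: sub for g, sub in cond_edges.groupby("gene_id")}
        active_regs = set(cond_edges["regulator_id"])
        for i in range(samples_per_condition):
            sid = f"{cancer}_{stage}_T{i:03d}"
            sheet_rows.append((sid, cancer, stage, "tumor"))
            # regulator log2 changes for this sample
            dm = np.zeros(len(mirnas))
            for j, m in enumerate(mirnas):
                shift = truth.mirna_shift[m]
                dm[j] = rng.normal(shift, 0.5) if shift != 0.0 \
                    else rng.normal(0, 0.3)
            dtf = {t: (rng.normal(truth.tf_shift[t], 0.5)
                       if t in active_regs else rng.normal(0, 0.3))
                   for t in truth.tf_ids}
            cnv_change = rng.normal(0, 0.3, len(genes))
            meth_change = rng.normal(0, 0.2, len(genes))
            dgene = np.zeros(len(all_gene_feats))
            for g_idx, g in enumerate(genes):
                delta = cnv_change[g_idx] - meth_change[g_idx] \
                    + rng.normal(0, noise_sd)
                sub = by_gene.get(g)
                if sub is not None:
                    for _, e in sub.iterrows():
                        dreg = (dm[mir_pos[e.regulator_id]]
                                if e.kind == "miRNA" else dtf[e.regulator_id])
                        delta += e.effect * dreg
                dgene[g_idx] = delta
            for t in truth.tf_ids:
                dgene[gene_pos[t]] = dtf[t]
            gene_cols[sid] = np.maximum(
                base_gene.to_numpy() * 2.0 ** dgene, 0.0)
            mir_cols[sid] = base_mir.to_numpy() * 2.0 ** dm
            cnv_cols[sid] = 2.0 * 2.0 ** cnv_change
            meth_cols[sid] = np.clip(0.5 + meth_change, 0.0, 1.0)

    sheet = pd.DataFrame(sheet_rows, columns=["sample_id", "cancer_type",
                                              "stage", "status"])
    gene_expr = pd.DataFrame(gene_cols, index=all_gene_feats)
    mirna_expr = pd.DataFrame(mir_cols, index=mirnas)
    cnv = pd.DataFrame(cnv_cols, index=genes)
    meth = pd.DataFrame(meth_cols, index=genes)
    return {"gene_expr": gene_expr, "mirna_expr": mirna_expr, "cnv": cnv,
            "methylation": meth, "sample_sheet": sheet}


def generate_pathways(truth: GroundTruthNetwork, n_pathways: int = 40,
                      size_range: tuple[int, int] = (8, 15),
                      seed: int = 5) -> dict[str, frozenset[str]]:
    """GMT-style pathway collection with the module's pathways planted.

    The planted module's target genes are co-assigned to each of the
    module's pathways (topped up with random genes); the remaining
    pathways draw members uniformly from the gene universe.
    """
    if size_range[0] < 5:
        raise ValueError("pathway sizes must be >= 5")
    if n_pathways < len(truth.module_pathways):
        raise ValueError("need at least as many pathways as the module uses")
    rng = np.random.default_rng(seed)
    out: dict[str, frozenset[str]] = {}
    for pw in truth.module_pathways:
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        members = set(truth.module_genes)
        extra = max(0, size - len(members))
        pool = [g for g in truth.gene_ids if g not in members]
        members |= set(rng.choice(pool, extra, replace=False))
        out[pw] = frozenset(members)
    i = len(truth.module_pathways)
    while len(out) < n_pathways:
        i += 1
        name = f"PW{i:03d}"
        if name in out:
            continue
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        out[name] = frozenset(rng.choice(truth.gene_ids, size, replace=False))
    return out


def generate_mutations(truth: GroundTruthNetwork, sites: pd.DataFrame,
                       fraction: float = 0.02, seed: int = 6) -> pd.DataFrame:
    """Somatic-mutation flags on a small fraction of decoy binding sites."""
    rng = np.random.default_rng(seed)
    decoy_sites = sites.loc[~sites["is_true"], "site_id"].tolist() \
        if "is_true" in sites.columns else sites["site_id"].tolist()
    n = int(round(fraction * len(decoy_sites)))
    rows = []
    for s in rng.choice(decoy_sites, n, replace=False) if n else []:
        cancer, stage = truth.conditions[rng.integers(len(truth.conditions))]
        rows.append({"site_id": s, "cancer_type": cancer, "stage": stage})
    return pd.DataFrame(rows, columns=["site_id", "cancer_type", "stage"])


@dataclass
class SyntheticBundle:
    """All pipeline inputs plus the planted truth."""

    truth: GroundTruthNetwork
    sites: pd.DataFrame
    mirna_singles: pd.Series
    mrna_singles: pd.Series
    tf_sites: pd.DataFrame
    gene_expr: pd.DataFrame
    mirna_expr: pd.DataFrame
    cnv: pd.DataFrame
    methylation: pd.DataFrame
    sample_sheet: pd.DataFrame
    pathways: dict[str, frozenset[str]]
    mutations: pd.DataFrame


def generate_bundle(seed: int = 1, *, noise_sd: float = 0.5,
                    samples_per_condition: int = 60,
                    normals_per_cancer: int = 30,
                    depth: float = 1.0,
                    **truth_kwargs) -> SyntheticBundle:
    """One call producing a mutually consistent full input bundle."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(6) % (2**31)]
    truth = generate_truth(seed=seeds[0], **truth_kwargs)
    ev = generate_binding_evidence(truth, depth=depth, seed=seeds[1])
    tf_sites = generate_tf_sites(truth, seed=seeds[2])
    expr = generate_expression(truth, samples_per_condition=samples_per_condition,
                               normals_per_cancer=normals_per_cancer,
                               noise_sd=noise_sd, seed=seeds[3])
    pathways = generate_pathways(truth, seed=seeds[4])
    mutations = generate_mutations(truth, ev["sites"], seed=seeds[5])
    return SyntheticBundle(truth=truth, sites=ev["sites"],
                           mirna_singles=ev["mirna_singles"],
                           mrna_singles=ev["mrna_singles"],
                           tf_sites=tf_sites, pathways=pathways,
                           mutations=mutations, **expr)


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> None:
    """Write the bundle as the file layout the pipeline reads, plus truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def _expr(df: pd.DataFrame, name: str) -> None:
        df.rename_axis("feature_id").to_csv(outdir / name, sep="\t",
                                            float_format="%.10g")

    bundle.sites.drop(columns=["is_true"]).to_csv(
        outdir / "binding_sites.tsv", sep="\t", index=False,
        float_format="%.10g")
    bundle.mirna_singles.reset_index().to_csv(
        outdir / "mirna_single_reads.tsv", sep="\t", index=False)
    bundle.mrna_singles.reset_index().to_csv(
        outdir / "mrna_single_reads.tsv", sep="\t", index=False)
    bundle.tf_sites.to_csv(outdir / "tf_sites.tsv", sep="\t", index=False)
    _expr(bundle.gene_expr, "gene_expression.tsv")
    _expr(bundle.mirna_expr, "mirna_expression.tsv")
    _expr(bundle.cnv, "cnv.tsv")
    _expr(bundle.methylation, "methylation.tsv")
    bundle.sample_sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t",
                               index=False)
    bundle.mutations.to_csv(outdir / "mutations.tsv", sep="\t", index=False)
    mio.write_gmt(bundle.pathways, outdir / "pathways.gmt")
    bundle.truth.edges.to_csv(outdir / "truth.tsv", sep="\t", index=False,
                              float_format="%.10g")
    module = {"mirnas": bundle.truth.module_mirnas,
              "genes": bundle.truth.module_genes,
              "pathways": bundle.truth.module_pathways,
              "conditions": [list(c) for c in bundle.truth.module_conditions],
              "seed": bundle.truth.seed}
    (outdir / "truth_module.json").write_text(json.dumps(module, indent=1))
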