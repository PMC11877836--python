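"""Synthetic genomes, methylomes and TE expression with planted ground truth.

The generator emulates the design of a multi-cell-type WGBS/RNA-seq study
of the male germline: one somatic reference (leaf) and three sex cell
types (meiocyte, microspore, pollen), two WGBS replicates each, with
per-cytosine calls drawn binomially at compartment-specific methylation
levels and Poisson sequencing depth.  Hypermethylated loci of three
classes are planted at known positions:

SLM
    Sex cells gain an additive per-context effect; the somatic background
    stays at the low intergenic level (low somatic RdDM activity).
SLH
    Same sex-cell gain, but the somatic background is itself an RdDM-like
    target (elevated leaf CHH/CHG), so the locus must classify as
    canonical SLH-like, never SLM-like.
DMR
    RdDM-target loci for the two-condition (wild type vs rdr2-like
    mutant) comparison: CHH drops from `rddm_wt_chh` to `rddm_mut_chh`.

TE expression counts are negative-binomial around per-cluster per-cell-
type mean TPM profiles, with inactive TEs at zero and genes at an
independent baseline.  Every random stream is seeded by (master seed,
output tag), so adding samples never perturbs existing ones.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from slmkit.io import CONTEXTS

COMPARTMENTS = ("intergenic", "gene_body", "te_body", "te_flank")

DEFAULT_COMPARTMENT_METH = {
    ("te_body", "CG"): 0.80, ("te_body", "CHG"): 0.50, ("te_body", "CHH"): 0.08,
    ("gene_body", "CG"): 0.20, ("gene_body", "CHG"): 0.03, ("gene_body", "CHH"): 0.01,
    ("te_flank", "CG"): 0.30, ("te_flank", "CHG"): 0.20, ("te_flank", "CHH"): 0.08,
    ("intergenic", "CG"): 0.10, ("intergenic", "CHG"): 0.05, ("intergenic", "CHH"): 0.02,
}


@dataclass
class ExprCluster:
    """One planted expression cluster: peak cell type, mean TPM profile, size."""

    name: str
    tpm: dict          # cell type -> mean TPM
    n_members: int


def default_expr_clusters(cell_types, n_tes: int) -> list:
    """Four clusters peaking in meiocyte, microspore, leaf and pollen, with a
    meiocyte-dominated size distribution as seen in germline TE activation.

    Roughly 40% of the simulated TEs are made active (desk-scale; real
    studies see a few percent of a much larger TE complement) and split
    across the peaks with meiocyte dominating.
    """
    proportions = {"meiocyte": 0.5, "microspore": 0.16, "leaf": 0.14, "pollen": 0.2}
    n_active = max(4, round(0.4 * n_tes))
    clusters = []
    for i, peak in enumerate(("meiocyte", "microspore", "leaf", "pollen"), start=1):
        if peak not in cell_types:
            continue
        tpm = {ct: (100.0 if ct == peak else 1.0) for ct in cell_types}
        clusters.append(ExprCluster(name=f"cluster{i}", tpm=tpm,
                                    n_members=max(1, round(proportions[peak] * n_active))))
    return clusters


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with study-design defaults."""

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 300_000
    n_genes: int = 80
    n_tes: int = 120
    te_superfamily_probs: dict = field(
        default_factory=lambda: {"Gypsy": 0.5, "Copia": 0.35, "other": 0.15})
    te_short_frac: float = 0.8            # fraction of TEs shorter than 2 kb
    te_short_range: tuple = (300, 1999)
    te_long_range: tuple = (2000, 8000)
    gene_length_range: tuple = (1000, 3000)
    te_flank_bp: int = 200
    min_feature_gap: int = 300
    compartment_meth: dict = field(
        default_factory=lambda: dict(DEFAULT_COMPARTMENT_METH))
    depth_mean: float = 20.0
    depth_overdispersion: float = 0.0     # 0 -> Poisson depth
    cell_types: tuple = ("leaf", "meiocyte", "microspore", "pollen")
    somatic: str = "leaf"
    n_replicates: int = 2
    n_planted_slm: int = 30
    n_planted_slh: int = 10
    n_planted_dmr: int = 100
    planted_len_range: tuple = (150, 350)
    slm_effect: dict = field(
        default_factory=lambda: {"CG": 0.3, "CHG": 0.3, "CHH": 0.3})
    slh_leaf_meth: dict = field(
        default_factory=lambda: {"CHG": 0.2, "CHH": 0.15})
    rddm_wt_chh: float = 0.25
    rddm_mut_chh: float = 0.02
    # fraction of SLM/SLH loci planted within `proximal_gap_range` of a gene,
    # mirroring the gene-targeting preference of sexual-lineage loci
    slm_gene_proximal: float = 0.6
    proximal_gap_range: tuple = (50, 400)
    expr_clusters: list = None
    expr_nb_size: float = 10.0
    library_size: float = 2_000_000.0
    gene_tpm_mean: float = 50.0
    active_short_bias: float = 8.0        # sampling weight of short TEs for activity

    def __post_init__(self):
        if self.expr_clusters is None:
            self.expr_clusters = default_expr_clusters(self.cell_types, self.n_tes)
        self.validate()

    def validate(self):
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        psum = sum(self.te_superfamily_probs.values())
        if abs(psum - 1.0) > 1e-9:
            raise ValueError(f"te_superfamily_probs must sum to 1 (got {psum})")
        for p in self.te_superfamily_probs.values():
            if not 0 <= p <= 1:
                raise ValueError("superfamily probabilities must lie in [0, 1]")
        for key, p in self.compartment_meth.items():
            if not 0 <= p <= 1:
                raise ValueError(f"compartment methylation {key} outside [0, 1]")
        if self.somatic not in self.cell_types:
            raise ValueError("somatic cell type must be one of cell_types")
        n_members = sum(c.n_members for c in self.expr_clusters)
        if n_members > self.n_tes:
            raise ValueError(
                f"expression clusters request {n_members} active TEs but only "
                f"{self.n_tes} TEs are simulated")

    @property
    def sex_cell_types(self):
        return tuple(ct for ct in self.cell_types if ct != self.somatic)


@dataclass
class GroundTruth:
    """Registry of everything the generator planted."""

    planted: pd.DataFrame        # chrom, start, end, cls in {SLM, SLH, DMR}
    te_activity: pd.DataFrame    # index te id: active flag, cluster (0 = none)
    chrom_sizes: dict

    def planted_of(self, *classes) -> pd.DataFrame:
        return self.planted[self.planted["cls"].isin(classes)].reset_index(drop=True)


def rng_for(seed: int, tag: str) -> np.random.Generator:
    """One independent, reproducible stream per (seed, output tag)."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(tag.encode())])


# --- genome and annotation ---------------------------------------------------

_BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
_BASE_P = np.array([0.32, 0.18, 0.18, 0.32])


def simulate_genome(config: SimConfig):
    """Random genome, non-overlapping gene/TE annotation, planted loci.

    Returns (genome, features, truth): genome is {chrom: sequence str};
    features is the annotation table (id, chrom, start, end, strand, kind,
    superfamily, length); truth records planted loci and TE activity.
    Raises if the requested features cannot be packed into the genome.
    """
    rng = rng_for(config.seed, "genome")
    chroms = [f"chr{i + 1}" for i in range(config.n_chrom)]
    genome = {}
    for chrom in chroms:
        seq = rng.choice(_BASES, size=config.chrom_length, p=_BASE_P)
        genome[chrom] = seq.tobytes().decode()

    # draw feature parts; a packing "item" is a list of (part, internal_gap)
    # so that a gene and a gene-proximal planted locus travel as one unit
    gene_parts, te_parts, planted_parts = [], [], []
    for i in range(config.n_genes):
        length = int(rng.integers(*config.gene_length_range, endpoint=True))
        gene_parts.append(["gene", "", length, f"gene{i + 1:04d}"])
    fams = list(config.te_superfamily_probs)
    fam_p = np.array([config.te_superfamily_probs[f] for f in fams])
    for i in range(config.n_tes):
        fam = fams[int(rng.choice(len(fams), p=fam_p))]
        if rng.random() < config.te_short_frac:
            length = int(rng.integers(*config.te_short_range, endpoint=True))
        else:
            length = int(rng.integers(*config.te_long_range, endpoint=True))
        te_parts.append(["TE", fam, length, f"te{i + 1:04d}"])
    planted_cls = (["SLM"] * config.n_planted_slm +
                   ["SLH"] * config.n_planted_slh +
                   ["DMR"] * config.n_planted_dmr)
    for j, cls in enumerate(planted_cls):
        length = int(rng.integers(*config.planted_len_range, endpoint=True))
        planted_parts.append(["planted", cls, length, f"planted{j + 1:04d}"])

    items = []
    free_genes = list(range(len(gene_parts)))
    for part in planted_parts:
        if part[1] in ("SLM", "SLH") and free_genes and \
                rng.random() < config.slm_gene_proximal:
            gi = free_genes.pop(int(rng.integers(len(free_genes))))
            inner = int(rng.integers(*config.proximal_gap_range, endpoint=True))
            pair = [(gene_parts[gi], 0), (part, inner)]
            if rng.random() < 0.5:  # locus upstream or downstream of the gene
                pair = [(part, 0), (gene_parts[gi], inner)]
            items.append(pair)
        else:
            items.append([(part, 0)])
    items.extend([(gene_parts[gi], 0)] for gi in free_genes)
    items.extend([(p, 0)] for p in te_parts)

    # pack: round-robin over chromosomes, random order within each
    order = rng.permutation(len(items))
    per_chrom = {c: [] for c in chroms}
    for k, idx in enumerate(order):
        per_chrom[chroms[k % len(chroms)]].append(items[idx])

    gap = config.min_feature_gap
    feature_rows, planted_rows = [], []
    for chrom in chroms:
        chrom_items = per_chrom[chrom]
        total = sum(part[2] + inner for it in chrom_items for part, inner in it)
        need = total + (len(chrom_items) + 1) * gap
        if need > config.chrom_length:
            n_parts = sum(len(it) for it in chrom_items)
            raise ValueError(
                f"infeasible packing on {chrom}: {n_parts} features of "
                f"total length {total} bp plus {gap} bp gaps need {need} bp, "
                f"but chrom_length is {config.chrom_length}")
        free = config.chrom_length - need
        extra = rng.multinomial(free, np.full(len(chrom_items) + 1,
                                              1.0 / (len(chrom_items) + 1)))
        pos = 0
        for it, pad in zip(chrom_items, extra[:-1]):
            pos += gap + int(pad)
            for part, inner in it:
                pos += inner
                kind, fam, length, name = part
                if kind == "planted":
                    planted_rows.append((chrom, pos, pos + length, fam))
                else:
                    strand = "+" if rng.random() < 0.5 else "-"
                    feature_rows.append((name, chrom, pos, pos + length, strand,
                                         kind, fam, length))
                pos += length

    features = pd.DataFrame(feature_rows, columns=[
        "id", "chrom", "start", "end", "strand", "kind", "superfamily", "length"])
    features = features.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    planted = pd.DataFrame(planted_rows, columns=["chrom", "start", "end", "cls"])
    planted = planted.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    te_activity = _assign_te_activity(features, config, rng)
    truth = GroundTruth(planted=planted, te_activity=te_activity,
                        chrom_sizes={c: config.chrom_length for c in chroms})
    return genome, features, truth


def _assign_te_activity(features: pd.DataFrame, config: SimConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    tes = features[features["kind"] == "TE"]
    n_active = sum(c.n_members for c in config.expr_clusters)
    weights = np.where(tes["length"] < 2000, config.active_short_bias, 1.0)
    weights = weights / weights.sum()
    chosen = rng.choice(tes["id"].to_numpy(), size=n_active, replace=False,
                        p=weights)
    cluster = {}
    i = 0
    for ci, spec in enumerate(config.expr_clusters, start=1):
        for te in chosen[i:i + spec.n_members]:
            cluster[te] = ci
        i += spec.n_members
    out = pd.DataFrame({
        "active": [te in cluster for te in tes["id"]],
        "cluster": [cluster.get(te, 0) for te in tes["id"]],
    }, index=pd.Index(tes["id"], name="te_id"))
    return out


# --- per-cytosine methylomes -------------------------------------------------

def context_scan(seq: str):
    """Strand-resolved cytosine positions and contexts of one sequence.

    Contexts are assigned from the reference trinucleotide downstream of
    the cytosine in its strand orientation: C-G -> CG, C-H-G -> CHG,
    C-H-H -> CHH.  Chromosome-end cytosines whose context cannot be
    resolved (fewer than the needed downstream bases) are omitted.

    Returns (pos0, strand, context) arrays sorted by (pos0, strand).
    """
    arr = np.frombuffer(seq.encode(), dtype="S1")
    n = len(arr)
    rows = []
    # plus strand: C at i, downstream i+1, i+2
    idx = np.flatnonzero(arr == b"C")
    for i in idx:
        if i + 1 >= n:
            continue
        if arr[i + 1] == b"G":
            rows.append((i, "+", "CG"))
        elif i + 2 < n:
            rows.append((i, "+", "CHG" if arr[i + 2] == b"G" else "CHH"))
    # minus strand: G at i, downstream i-1, i-2 (reverse complement)
    idx = np.flatnonzero(arr == b"G")
    for i in idx:
        if i - 1 < 0:
            continue
        if arr[i - 1] == b"C":
            rows.append((i, "-", "CG"))
        elif i - 2 >= 0:
            rows.append((i, "-", "CHG" if arr[i - 2] == b"C" else "CHH"))
    rows.sort()
    pos0 = np.array([r[0] for r in rows], dtype=np.int64)
    strand = np.array([r[1] for r in rows])
    context = np.array([r[2] for r in rows])
    return pos0, strand, context


def _context_scan_fast(seq: str):
    """Vectorised context_scan (same output, used internally)."""
    arr = np.frombuffer(seq.encode(), dtype="S1")
    n = len(arr)
    out_pos, out_strand, out_ctx = [], [], []

    plus = np.flatnonzero(arr[:-1] == b"C")
    n1 = arr[plus + 1]
    is_cg = n1 == b"G"
    has2 = plus + 2 < n
    n2 = np.where(has2, arr[np.minimum(plus + 2, n - 1)], b"N")
    ctx = np.where(is_cg, "CG", np.where(n2 == b"G", "CHG", "CHH"))
    keep = is_cg | has2
    out_pos.append(plus[keep]); out_strand.append(np.full(keep.sum(), "+"))
    out_ctx.append(ctx[keep])

    minus = np.flatnonzero(arr[1:] == b"G") + 1
    n1 = arr[minus - 1]
    is_cg = n1 == b"C"
    has2 = minus - 2 >= 0
    n2 = np.where(has2, arr[np.maximum(minus - 2, 0)], b"N")
    ctx = np.where(is_cg, "CG", np.where(n2 == b"C", "CHG", "CHH"))
    keep = is_cg | has2
    out_pos.append(minus[keep]); out_strand.append(np.full(keep.sum(), "-"))
    out_ctx.append(ctx[keep])

    pos0 = np.concatenate(out_pos)
    strand = np.concatenate(out_strand)
    context = np.concatenate(out_ctx)
    order = np.lexsort((strand, pos0))
    return pos0[order], strand[order], context[order]


def _compartment_codes(chrom_len: int, features: pd.DataFrame,
                       chrom: str, flank: int) -> np.ndarray:
    comp = np.zeros(chrom_len, dtype=np.int8)  # 0 = intergenic
    codes = {name: i for i, name in enumerate(COMPARTMENTS)}
    sub = features[features["chrom"] == chrom]
    for row in sub.itertuples():
        if row.kind == "TE":
            lo = max(0, row.start - flank)
            hi = min(chrom_len, row.end + flank)
            comp[lo:row.start] = codes["te_flank"]
            comp[row.end:hi] = codes["te_flank"]
    for row in sub.itertuples():
        if row.kind == "gene":
            comp[row.start:row.end] = codes["gene_body"]
    for row in sub.itertuples():
        if row.kind == "TE":
            comp[row.start:row.end] = codes["te_body"]
    return comp


def _base_probs(config: SimConfig, comp_code: np.ndarray,
                context: np.ndarray) -> np.ndarray:
    p = np.zeros(len(comp_code))
    for ci, comp in enumerate(COMPARTMENTS):
        for ctx in CONTEXTS:
            mask = (comp_code == ci) & (context == ctx)
            p[mask] = config.compartment_meth[(comp, ctx)]
    return p


def _interval_mask(pos0: np.ndarray, intervals: pd.DataFrame, chrom: str) -> np.ndarray:
    mask = np.zeros(len(pos0), dtype=bool)
    for row in intervals[intervals["chrom"] == chrom].itertuples():
        mask |= (pos0 >= row.start) & (pos0 < row.end)
    return mask


def _draw_depth(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    if config.depth_overdispersion > 0:
        shape = 1.0 / config.depth_overdispersion
        lam = rng.gamma(shape, config.depth_mean / shape, size=n)
        return rng.poisson(lam)
    return rng.poisson(config.depth_mean, size=n)


def _scan_genome(genome: dict):
    scans = {}
    for chrom, seq in genome.items():
        scans[chrom] = _context_scan_fast(seq)
    return scans


def simulate_methylome(genome: dict, features: pd.DataFrame, truth: GroundTruth,
                       config: SimConfig) -> dict:
    """Per-cell-type replicate CytosineCall tables with planted effects.

    Returns {cell_type: [replicate DataFrame, ...]}.  Sex cell types carry
    the planted SLM/SLH gains; the somatic type carries the elevated
    SLH-locus background but no gain.  Planted DMR loci are left at
    baseline here (they belong to the two-condition comparison).
    """
    scans = _scan_genome(genome)
    slm = truth.planted_of("SLM")
    slh = truth.planted_of("SLH")

    per_chrom_p = {}
    for chrom, (pos0, strand, context) in scans.items():
        comp = _compartment_codes(len(genome[chrom]), features, chrom,
                                  config.te_flank_bp)
        base = _base_probs(config, comp[pos0], context)
        slh_mask = _interval_mask(pos0, slh, chrom)
        for ctx, level in config.slh_leaf_meth.items():
            base[slh_mask & (context == ctx)] = level
        gain = np.zeros_like(base)
        planted_mask = _interval_mask(pos0, slm, chrom) | slh_mask
        for ctx, eff in config.slm_effect.items():
            gain[planted_mask & (context == ctx)] = eff
        per_chrom_p[chrom] = (pos0, strand, context, base, gain)

    out = {}
    for cell_type in config.cell_types:
        is_sex = cell_type != config.somatic
        reps = []
        for rep in range(1, config.n_replicates + 1):
            rng = rng_for(config.seed, f"meth:{cell_type}:{rep}")
            frames = []
            for chrom in sorted(genome):
                pos0, strand, context, base, gain = per_chrom_p[chrom]
                p = np.clip(base + (gain if is_sex else 0.0), 0.0, 1.0)
                total = _draw_depth(rng, len(pos0), config)
                meth = rng.binomial(total, p)
                frames.append(pd.DataFrame({
                    "chrom": chrom, "pos": pos0 + 1, "strand": strand,
                    "context": context, "meth": meth, "total": total}))
            reps.append(pd.concat(frames, ignore_index=True))
        out[cell_type] = reps
    return out


def simulate_condition_pair(genome: dict, features: pd.DataFrame,
                            truth: GroundTruth, config: SimConfig,
                            tags=("wt", "mut")) -> tuple:
    """Somatic-background methylomes for a WT vs RdDM-mutant comparison.

    Planted DMR loci sit at `rddm_wt_chh` CHH in the first condition and
    `rddm_mut_chh` in the second; everything else is identical baseline.
    Returns (wt_table, mut_table).
    """
    scans = _scan_genome(genome)
    dmr = truth.planted_of("DMR")
    tables = []
    for tag, chh_level in zip(tags, (config.rddm_wt_chh, config.rddm_mut_chh)):
        rng = rng_for(config.seed, f"cond:{tag}")
        frames = []
        for chrom in sorted(genome):
            pos0, strand, context = scans[chrom]
            comp = _compartment_codes(len(genome[chrom]), features, chrom,
                                      config.te_flank_bp)
            p = _base_probs(config, comp[pos0], context)
            mask = _interval_mask(pos0, dmr, chrom) & (context == "CHH")
            p[mask] = chh_level
            total = _draw_depth(rng, len(pos0), config)
            meth = rng.binomial(total, np.clip(p, 0, 1))
            frames.append(pd.DataFrame({
                "chrom": chrom, "pos": pos0 + 1, "strand": strand,
                "context": context, "meth": meth, "total": total}))
        tables.append(pd.concat(frames, ignore_index=True))
    return tables[0], tables[1]


# --- expression --------------------------------------------------------------

def simulate_expression(features: pd.DataFrame, truth: GroundTruth,
                        config: SimConfig):
    """Negative-binomial count matrix for genes and TEs.

    Active TEs follow their planted cluster's mean TPM profile; inactive
    TEs have zero expression (TPM < 0.001 in all samples); genes get an
    independent lognormal baseline shared across cell types.  Counts are
    gamma-Poisson with dispersion `expr_nb_size`.

    Returns (counts, lengths): counts is features x cell types.
    """
    rng = rng_for(config.seed, "expression")
    ids = features["id"].tolist()
    lengths = pd.Series(features["length"].to_numpy(), index=ids, dtype=float)

    tpm_target = pd.DataFrame(0.0, index=ids, columns=list(config.cell_types))
    genes = features.loc[features["kind"] == "gene", "id"]
    if config.gene_tpm_mean > 0:
        baseline = rng.lognormal(mean=np.log(config.gene_tpm_mean), sigma=0.5,
                                 size=len(genes))
    else:
        baseline = np.zeros(len(genes))
    for ct in config.cell_types:
        tpm_target.loc[genes, ct] = baseline
    for te_id, row in truth.te_activity.iterrows():
        if not row["active"]:
            continue
        spec = config.expr_clusters[int(row["cluster"]) - 1]
        for ct in config.cell_types:
            tpm_target.loc[te_id, ct] = spec.tpm[ct]

    counts = pd.DataFrame(0, index=ids, columns=list(config.cell_types),
                          dtype=np.int64)
    for ct in config.cell_types:
        w = tpm_target[ct].to_numpy() * lengths.to_numpy()
        total = w.sum()
        mu = config.library_size * w / total if total > 0 else np.zeros_like(w)
        size = config.expr_nb_size
        lam = np.where(mu > 0, rng.gamma(size, 1.0, size=len(mu)) * mu / size, 0.0)
        counts[ct] = rng.poisson(lam)
    return counts, lengths


def simulate_deg_table(features: pd.DataFrame, slm_target_genes, config: SimConfig) -> pd.DataFrame:
    """Emulated differential-expression statistics table (gene, contrast,
    log2fc, pvalue).

    Model fitting is upstream of this package; for end-to-end runs this
    emits a plausible table in which a majority of SLM-targeted genes are
    significantly regulated (mostly down, persisting across stages) and
    other genes are null.
    """
    rng = rng_for(config.seed, "deg")
    genes = features.loc[features["kind"] == "gene", "id"].tolist()
    slm_set = set(slm_target_genes)
    contrasts = [f"{ct}_vs_{config.somatic}" for ct in config.sex_cell_types]
    rows = []
    for gene in genes:
        if gene in slm_set and rng.random() < 0.65:
            down = rng.random() < 0.66
            persists = rng.random() < 0.9
            for i, contrast in enumerate(contrasts):
                if down and (i == 0 or persists):
                    lfc = -float(rng.uniform(1.2, 4.0))
                    p = float(10 ** rng.uniform(-12, -3))
                elif not down and i == int(rng.integers(len(contrasts))):
                    lfc = float(rng.uniform(1.2, 4.0))
                    p = float(10 ** rng.uniform(-8, -2))
                else:
                    lfc = float(rng.normal(0, 0.3))
                    p = float(rng.uniform(0.1, 1.0))
                rows.append((gene, contrast, lfc, p))
        else:
            for contrast in contrasts:
                rows.append((gene, contrast, float(rng.normal(0, 0.3)),
                             float(rng.uniform(0.05, 1.0))))
    return pd.DataFrame(rows, columns=["gene", "contrast", "log2fc", "pvalue"])


# --- on-disk outputs ---------------------------------------------------------

def write_fasta(genome: dict, path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=chrom, description="")
               for chrom, seq in sorted(genome.items())]
    SeqIO.write(records, str(path), "fasta")


def write_truth(truth: GroundTruth, path) -> None:
    payload = {
        "planted": truth.planted.to_dict(orient="records"),
        "te_activity": truth.te_activity.reset_index().to_dict(orient="records"),
        "chrom_sizes": truth.chrom_sizes,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
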