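"""Synthetic inputs with planted ground truth.

Every input class the pipeline consumes can be generated here at desk scale:
a random genome, motif-driven TF track signal (Poisson counts over smoothed
motif occupancy), SNV panels in which regulatory variants are exactly those
whose allele swap creates or destroys a motif occurrence, an eQTL-structured
expression cohort, case-control GWAS summary statistics, and the annotation
tables (chromatin states, pathogenic variants, CERES dependency scores,
drug-target and disease-gene pairs) with known enrichment structure.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tcra import Variant

#: The 15-state chromatin vocabulary (Roadmap core model); enhancer states
#: are 6_EnhG and 7_Enh by default.
CHROMHMM_15_STATES = [
    "1_TssA", "2_TssAFlnk", "3_TxFlnk", "4_Tx", "5_TxWk", "6_EnhG", "7_Enh",
    "8_ZNF/Rpts", "9_Het", "10_TssBiv", "11_BivFlnk", "12_EnhBiv",
    "13_ReprPC", "14_ReprPCWk", "15_Quies",
]
ENHANCER_STATES = ("6_EnhG", "7_Enh")


@dataclasses.dataclass
class SyntheticGenome:
    chrom_names: list[str]
    sequences: list[str]
    seed: int

    def __post_init__(self):
        for s in self.sequences:
            if not s or set(s) - set("ACGTN"):
                raise ValueError("sequences must be nonempty strings over {A,C,G,T,N}")

    # GenomeLike protocol
    def chroms(self) -> list[str]:
        return list(self.chrom_names)

    def length(self, chrom: str) -> int:
        return len(self.sequences[self.chrom_names.index(chrom)])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequences[self.chrom_names.index(chrom)]
        if start < 0 or end > len(seq) or start > end:
            raise IndexError(f"interval [{start}, {end}) outside {chrom}")
        return seq[start:end]

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.chrom_names, self.sequences))


@dataclasses.dataclass
class TrackTruthModel:
    """Generative model for per-bp TF track signal.

    Signal is Poisson with rate ``background_rate + peak_rate * occupancy``.
    Occupancy is PWM-like and graded: a full consensus match contributes
    credit 1 and a one-mismatch site contributes ``partial_credit`` (weak
    affinity binding), each spread by an unnormalized fixed-width boxcar so
    peaks reach the 10-30x fold enrichment typical of ChIP-seq read pileups
    and span a sizeable fraction of a 128-bp output bin.
    """

    k: int
    motifs: list[str]
    background_rate: float = 0.5
    peak_rate: float = 8.0
    seed: int = 0
    smooth_width: int = 50
    partial_credit: float = 0.25

    def __post_init__(self):
        if self.k < 1 or len(self.motifs) != self.k:
            raise ValueError("need one motif per track (k >= 1)")
        if self.background_rate < 0 or self.peak_rate < 0:
            raise ValueError("rates must be nonnegative")


@dataclasses.dataclass
class PlantedVariantPanel:
    variants: list[Variant]
    is_regulatory: np.ndarray  # bool per variant

    def __post_init__(self):
        self.is_regulatory = np.asarray(self.is_regulatory, dtype=bool)
        if len(self.variants) != self.is_regulatory.shape[0]:
            raise ValueError("flag vector length mismatch")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [v.id for v in self.variants],
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "ref": [v.ref for v in self.variants],
                "alt": [v.alt for v in self.variants],
                "is_regulatory": self.is_regulatory,
            }
        )


@dataclasses.dataclass
class GeneDef:
    gene: str
    chrom: str
    tss: int  # 1-based
    causal: list[tuple[str, float]]  # (variant id, effect size)


@dataclasses.dataclass
class CohortTruth:
    genotypes: np.ndarray  # (n_samples, n_variants) dosages in {0,1,2}
    variant_ids: list[str]
    mafs: np.ndarray
    causal_map: dict[str, list[tuple[str, float]]]
    h2: float
    covariates: np.ndarray  # (n_samples, c)
    covariate_effects: np.ndarray  # (c, n_genes)


@dataclasses.dataclass
class AnnotationFixtures:
    states: dict[str, pd.DataFrame]  # cell line -> (chrom,start,end,state)
    tissue_cell_lines: list[str]
    other_cell_lines: list[str]
    pathogenic: pd.DataFrame
    ceres: pd.DataFrame
    drug_targets: pd.DataFrame
    disease_genes: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------- genome


def make_genome(n_chrom: int, length_per_chrom: int, seed: int, prefix: str = "chr") -> SyntheticGenome:
    """Uniform-random genome; deterministic under seed."""
    if n_chrom < 1 or length_per_chrom < 1:
        raise ValueError("n_chrom and length_per_chrom must be >= 1")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    names, seqs = [], []
    for i in range(n_chrom):
        names.append(f"{prefix}{i + 1}")
        seqs.append("".join(bases[rng.integers(0, 4, length_per_chrom)]))
    return SyntheticGenome(names, seqs, seed)


def inject_n_runs(genome: SyntheticGenome, n_runs: int, run_length: int, seed: int) -> SyntheticGenome:
    """Return a copy with N runs injected (for encoder-handling tests)."""
    rng = np.random.default_rng(seed)
    seqs = []
    for seq in genome.sequences:
        s = list(seq)
        for _ in range(n_runs):
            start = int(rng.integers(0, max(1, len(s) - run_length)))
            s[start : start + run_length] = "N" * run_length
        seqs.append("".join(s))
    return SyntheticGenome(list(genome.chrom_names), seqs, genome.seed)


# ---------------------------------------------------------------- tracks


def motif_occurrences(seq: str, motif: str) -> list[int]:
    """Start positions of (possibly overlapping) exact motif matches."""
    out, i = [], seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


def _match_counts(seq: str, motif: str) -> np.ndarray:
    """Per-site consensus match counts for every start position."""
    s = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    m = np.frombuffer(motif.encode("ascii"), dtype=np.uint8)
    n_sites = len(s) - len(m) + 1
    if n_sites <= 0:
        return np.zeros(0, dtype=np.int64)
    counts = np.zeros(n_sites, dtype=np.int64)
    for j, mj in enumerate(m):
        counts += s[j : j + n_sites] == mj
    return counts


def _occupancy(seq: str, motif: str, smooth_width: int, partial_credit: float) -> np.ndarray:
    counts = _match_counts(seq, motif)
    ell = len(motif)
    credit = np.where(counts == ell, 1.0, np.where(counts == ell - 1, partial_credit, 0.0))
    ind = np.zeros(len(seq))
    centers = np.arange(len(credit)) + ell // 2
    np.add.at(ind, np.minimum(centers, len(seq) - 1), credit)
    if smooth_width > 1:
        ind = np.convolve(ind, np.ones(smooth_width), mode="same")
    return ind


def track_rates(genome: SyntheticGenome, truth: TrackTruthModel) -> dict[str, np.ndarray]:
    """Expected (Poisson rate) signal per chrom, (L, k)."""
    out = {}
    for chrom, seq in zip(genome.chrom_names, genome.sequences):
        lam = np.empty((len(seq), truth.k))
        for j, motif in enumerate(truth.motifs):
            lam[:, j] = truth.background_rate + truth.peak_rate * _occupancy(
                seq, motif, truth.smooth_width, truth.partial_credit
            )
        out[chrom] = lam
    return out


def simulate_tracks(genome: SyntheticGenome, truth: TrackTruthModel) -> dict[str, np.ndarray]:
    """Per-bp Poisson counts for each track; deterministic under truth.seed."""
    if not genome.chrom_names:
        raise ValueError("empty genome")
    rng = np.random.default_rng(truth.seed)
    return {c: rng.poisson(lam).astype(np.float64) for c, lam in track_rates(genome, truth).items()}


# ---------------------------------------------------------------- variants


def _local_flip(seq: str, pos0: int, alt: str, motifs: Sequence[str]) -> bool:
    """Does swapping seq[pos0] -> alt change any motif occurrence count?

    Only the neighbourhood that can host an occurrence overlapping pos0 is
    scanned, for both alleles.
    """
    for motif in motifs:
        m = len(motif)
        lo, hi = max(0, pos0 - m + 1), min(len(seq), pos0 + m)
        ref_local = seq[lo:hi]
        alt_local = ref_local[: pos0 - lo] + alt + ref_local[pos0 - lo + 1 :]
        if len(motif_occurrences(ref_local, motif)) != len(motif_occurrences(alt_local, motif)):
            return True
    return False


def plant_variants(
    genome: SyntheticGenome,
    truth: TrackTruthModel,
    n_variants: int,
    frac_regulatory: float,
    seed: int,
    edge_margin: int = 0,
) -> PlantedVariantPanel:
    """Plant SNVs; a ``frac_regulatory`` fraction flips a motif occurrence.

    Regulatory variants are placed inside existing motif occurrences with an
    alt allele that destroys the match; flags are verified by re-scanning
    both alleles. Non-regulatory variants are rejection-sampled so neither
    allele changes any motif occurrence count.
    """
    if not 0 <= frac_regulatory <= 1:
        raise ValueError("frac_regulatory must be in [0, 1]")
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    n_reg = round(n_variants * frac_regulatory)

    # candidate regulatory sites: positions inside motif occurrences
    candidates = []
    for chrom, seq in zip(genome.chrom_names, genome.sequences):
        for motif in truth.motifs:
            for p in motif_occurrences(seq, motif):
                for off in range(len(motif)):
                    pos0 = p + off
                    if edge_margin <= pos0 < len(seq) - edge_margin:
                        candidates.append((chrom, pos0))
    candidates = sorted(set(candidates))
    if len(candidates) < n_reg:
        raise ValueError(
            f"genome hosts only {len(candidates)} motif-overlapping positions; "
            f"{n_reg} regulatory variants requested"
        )
    rng.shuffle(candidates)

    used: set[tuple[str, int]] = set()
    entries: list[tuple[str, int, str, str, bool]] = []
    seq_of = genome.as_dict()

    for chrom, pos0 in candidates[:n_reg]:
        seq = seq_of[chrom]
        ref = seq[pos0]
        alts = [b for b in bases if b != ref and _local_flip(seq, pos0, b, truth.motifs)]
        alt = alts[int(rng.integers(len(alts)))]
        entries.append((chrom, pos0, ref, alt, True))
        used.add((chrom, pos0))

    n_nonreg = n_variants - n_reg
    attempts = 0
    while sum(1 for e in entries if not e[4]) < n_nonreg:
        attempts += 1
        if attempts > 200 * max(1, n_nonreg):
            raise ValueError("genome too dense in motifs to host neutral variants")
        ci = int(rng.integers(len(genome.chrom_names)))
        chrom = genome.chrom_names[ci]
        seq = seq_of[chrom]
        if len(seq) <= 2 * edge_margin:
            raise ValueError("chromosome shorter than twice the edge margin")
        pos0 = int(rng.integers(edge_margin, len(seq) - edge_margin))
        if (chrom, pos0) in used:
            continue
        ref = seq[pos0]
        alt = bases[int(rng.integers(4))]
        if alt == ref or _local_flip(seq, pos0, alt, truth.motifs):
            continue
        entries.append((chrom, pos0, ref, alt, False))
        used.add((chrom, pos0))

    entries.sort(key=lambda e: (e[0], e[1]))
    variants = [
        Variant(chrom, pos0 + 1, ref, alt, id=f"snv{i:05d}")
        for i, (chrom, pos0, ref, alt, _) in enumerate(entries)
    ]
    flags = np.array([e[4] for e in entries], dtype=bool)
    return PlantedVariantPanel(variants, flags)


# ---------------------------------------------------------------- cohort


def define_genes(
    panel: PlantedVariantPanel,
    n_genes: int,
    n_causal: int,
    effect_size: float,
    seed: int,
    causal_genes: int | None = None,
    tss_jitter: int = 5_000,
) -> list[GeneDef]:
    """Assign genes a TSS near their (distinct) causal variants.

    ``causal_genes`` limits how many genes actually carry nonzero effects;
    the remainder are null genes whose TSS sits near unrelated variants.
    """
    rng = np.random.default_rng(seed)
    if causal_genes is None:
        causal_genes = n_genes
    order = rng.permutation(len(panel.variants))
    need = n_genes * n_causal
    if need > len(panel.variants):
        raise ValueError("not enough variants for the requested gene definitions")
    genes = []
    for g in range(n_genes):
        vids = order[g * n_causal : (g + 1) * n_causal]
        anchor = panel.variants[int(vids[0])]
        tss = max(1, anchor.pos + int(rng.integers(-tss_jitter, tss_jitter + 1)))
        if g < causal_genes:
            causal = [
                (panel.variants[int(v)].id, effect_size * (1 if rng.random() < 0.5 else -1))
                for v in vids
            ]
        else:
            causal = []
        genes.append(GeneDef(f"gene{g:03d}", anchor.chrom, tss, causal))
    return genes


def simulate_cohort(
    panel: PlantedVariantPanel,
    n_samples: int,
    maf_range: tuple[float, float],
    gene_defs: Sequence[GeneDef],
    h2: float,
    seed: int,
    n_covariates: int = 2,
) -> tuple[CohortTruth, pd.DataFrame, pd.DataFrame]:
    """Genotype dosages + eQTL-structured expression.

    Dosages are Binomial(2, maf) draws; expression is the causal genetic
    component plus covariate effects plus Gaussian noise scaled so the
    genetic fraction of the non-covariate variance equals ``h2``.
    Returns (truth, genotypes samples x variants, expression samples x genes).
    """
    if not (0 < maf_range[0] <= maf_range[1] <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    if not gene_defs:
        raise ValueError("gene_defs is empty")
    if not 0 <= h2 <= 1:
        raise ValueError("h2 must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    nv = len(panel.variants)
    ids = [v.id for v in panel.variants]
    mafs = rng.uniform(maf_range[0], maf_range[1], nv)
    geno = rng.binomial(2, mafs, size=(n_samples, nv)).astype(np.float64)
    cov = rng.normal(0, 1, (n_samples, n_covariates))
    cov_eff = rng.normal(0, 0.5, (n_covariates, len(gene_defs)))
    idx = {vid: j for j, vid in enumerate(ids)}

    expr = np.empty((n_samples, len(gene_defs)))
    causal_map = {}
    for g, gd in enumerate(gene_defs):
        causal_map[gd.gene] = list(gd.causal)
        genetic = np.zeros(n_samples)
        if h2 > 0:
            for vid, eff in gd.causal:
                genetic += eff * geno[:, idx[vid]]
        var_g = genetic.var()
        if h2 > 0 and var_g > 0:
            noise_sd = np.sqrt(var_g * (1 - h2) / h2) if h2 < 1 else 0.0
        else:
            genetic = np.zeros(n_samples)
            noise_sd = 1.0
        expr[:, g] = genetic + cov @ cov_eff[:, g] + rng.normal(0, noise_sd, n_samples)

    samples = [f"s{i:04d}" for i in range(n_samples)]
    truth = CohortTruth(geno, ids, mafs, causal_map, h2, cov, cov_eff)
    geno_df = pd.DataFrame(geno, index=samples, columns=ids)
    expr_df = pd.DataFrame(expr, index=samples, columns=[g.gene for g in gene_defs])
    return truth, geno_df, expr_df


# ---------------------------------------------------------------- GWAS


def simulate_gwas_summary(
    panel: PlantedVariantPanel,
    causal_effects: Mapping[str, float],
    n_cases: int,
    n_controls: int,
    seed: int,
    freqs: Mapping[str, float] | None = None,
    method: str = "analytic",
) -> pd.DataFrame:
    """Case-control summary statistics (beta, se, p, freq) per SNV.

    ``analytic`` (default) draws beta ~ Normal(true effect, se) with the
    standard log-odds standard error from allele frequency and effective
    sample size. ``individual`` simulates genotypes and case status per SNV
    and fits a logistic regression (slow; kept for validation).
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    n_eff = n_cases * n_controls / (n_cases + n_controls)
    for v in panel.variants:
        f = float(freqs[v.id]) if freqs is not None else float(rng.uniform(0.05, 0.5))
        true_beta = float(causal_effects.get(v.id, 0.0))
        if method == "analytic":
            se = 1.0 / np.sqrt(2 * f * (1 - f) * n_eff)
            beta = float(rng.normal(true_beta, se))
        elif method == "individual":
            beta, se, f = _logistic_snv(rng, f, true_beta, n_cases, n_controls)
        else:
            raise ValueError(f"unknown method {method!r}")
        from scipy import stats

        p = float(2 * stats.norm.sf(abs(beta / se)))
        rows.append((v.id, v.chrom, v.pos, v.ref, v.alt, beta, se, p, f))
    return pd.DataFrame(
        rows, columns=["id", "chrom", "pos", "ref", "alt", "beta", "se", "p", "freq"]
    )


def _logistic_snv(rng, f, true_beta, n_cases, n_controls):
    """One-SNV individual-level case-control draw + logistic fit."""
    import statsmodels.api as sm

    n = n_cases + n_controls
    g = rng.binomial(2, f, n).astype(float)
    b0 = np.log(n_cases / n_controls) - true_beta * 2 * f
    prob = 1 / (1 + np.exp(-(b0 + true_beta * g)))
    y = (rng.random(n) < prob).astype(float)
    X = sm.add_constant(g)
    fit = sm.Logit(y, X).fit(disp=0)
    return float(fit.params[1]), float(fit.bse[1]), float(g.mean() / 2)


# ---------------------------------------------------------------- annotations


def make_annotation_fixtures(
    panel: PlantedVariantPanel,
    genes: Sequence[str],
    seed: int,
    enhancer_enrichment: float = 3.0,
    p_base: float = 0.15,
    n_tissue_cell_lines: int = 2,
    n_other_cell_lines: int = 2,
    n_pathogenic: int = 10,
    n_ceres_cell_lines: int = 10,
    essential_genes: Sequence[str] | None = None,
    druggable_genes: Sequence[str] | None = None,
    disease_listed_genes: Sequence[str] | None = None,
) -> AnnotationFixtures:
    """Annotation tables with planted enrichment structure.

    In tissue cell lines, enhancer intervals cover regulatory variants with
    probability ``enhancer_enrichment * p_base`` and non-regulatory variants
    with ``p_base``; unrelated cell lines cover all variants at ``p_base``.
    Designated essential genes receive CERES scores clipped below -0.55 so
    their median is < -0.5 by construction.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    if essential_genes is None:
        essential_genes = genes[: max(1, len(genes) // 5)]
    if druggable_genes is None:
        druggable_genes = genes[max(1, len(genes) // 5) : 2 * max(1, len(genes) // 5)]
    if disease_listed_genes is None:
        disease_listed_genes = genes[: max(1, int(round(0.45 * len(genes))))]

    p_reg = min(1.0, enhancer_enrichment * p_base)
    states: dict[str, pd.DataFrame] = {}
    cell_lines = [(f"tissueCL{i + 1}", True) for i in range(n_tissue_cell_lines)] + [
        (f"otherCL{i + 1}", False) for i in range(n_other_cell_lines)
    ]
    non_enh = [s for s in CHROMHMM_15_STATES if s not in ENHANCER_STATES]
    for name, is_tissue in cell_lines:
        rows = []
        for v, reg in zip(panel.variants, panel.is_regulatory):
            p = (p_reg if reg else p_base) if is_tissue else p_base
            p0 = v.pos - 1
            if rng.random() < p:
                start = max(0, p0 - int(rng.integers(5, 50)))
                end = p0 + int(rng.integers(5, 50))
                rows.append((v.chrom, start, end, ENHANCER_STATES[int(rng.integers(2))]))
            else:
                # non-enhancer state covering the variant, plus background
                start = max(0, p0 - int(rng.integers(5, 50)))
                end = p0 + int(rng.integers(5, 50))
                rows.append((v.chrom, start, end, non_enh[int(rng.integers(len(non_enh)))]))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
        states[name] = df.sort_values(["chrom", "start"]).reset_index(drop=True)

    # pathogenic table: planted pathogenic+germline rows plus decoys
    order = rng.permutation(len(panel.variants))
    path_ids = [panel.variants[int(i)].id for i in order[:n_pathogenic]]
    decoys = [panel.variants[int(i)].id for i in order[n_pathogenic : n_pathogenic + 10]]
    vmap = {v.id: v for v in panel.variants}
    prows = []
    for vid in path_ids:
        v = vmap[vid]
        prows.append((v.chrom, v.pos, v.ref, v.alt, "pathogenic", "germline"))
    for j, vid in enumerate(decoys):
        v = vmap[vid]
        sig, origin = ("pathogenic", "somatic") if j % 2 == 0 else ("benign", "germline")
        prows.append((v.chrom, v.pos, v.ref, v.alt, sig, origin))
    pathogenic = pd.DataFrame(
        prows, columns=["chrom", "pos", "ref", "alt", "clinical_significance", "origin"]
    )

    crows = []
    for g in genes:
        for c in range(n_ceres_cell_lines):
            if g in essential_genes:
                score = min(-0.55, float(rng.normal(-1.0, 0.2)))
            else:
                score = float(rng.normal(0.0, 0.2))
            crows.append((g, f"cellline{c:02d}", score))
    ceres = pd.DataFrame(crows, columns=["gene", "cell_line", "score"])

    statuses = ["approved", "phase II", "phase III"]
    drows = []
    for j, g in enumerate(druggable_genes):
        drows.append((g, f"drug{j:03d}", statuses[j % 3]))
    # genes with only non-actionable records must not count as druggable
    for j, g in enumerate(genes[-2:]):
        if g not in druggable_genes:
            drows.append((g, f"drugX{j:02d}", "other"))
    drug_targets = pd.DataFrame(drows, columns=["gene", "drug", "status"])

    disease_genes = pd.DataFrame(
        [(g, "synthetic_disease") for g in disease_listed_genes],
        columns=["gene", "disease"],
    )

    truth = {
        "pathogenic_germline_ids": path_ids,
        "essential_genes": list(essential_genes),
        "druggable_genes": list(druggable_genes),
        "disease_listed_genes": list(disease_listed_genes),
        "p_base": p_base,
        "enhancer_enrichment": enhancer_enrichment,
    }
    return AnnotationFixtures(
        states=states,
        tissue_cell_lines=[n for n, t in cell_lines if t],
        other_cell_lines=[n for n, t in cell_lines if not t],
        pathogenic=pathogenic,
        ceres=ceres,
        drug_targets=drug_targets,
        disease_genes=disease_genes,
        truth=truth,
    )
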