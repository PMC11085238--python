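"""Synthetic germplasm panels, bi-parental RILs and multi-environment phenotypes.

The generator emulates the structure the downstream analysis assumes: six
germplasm panels (A–F, default sizes summing to 4141 accessions) split into
a cultivated cluster I (A–D) and a diverged wild cluster II (E, F); a
bi-parental F2:6 recombinant-inbred-line population of 175 lines developed
by single seed descent; and two polygenic traits (oil and protein content,
%) with strongly negatively correlated QTL effects, phenotyped in a
replicated multi-environment trial at line-mean broad-sense heritability
≈ 0.9.

Panel structure follows a hierarchical Balding–Nichols drift model:
ancestral allele frequencies are perturbed first at the cluster level
(fst_between_cluster) and then at the panel level (fst_within_cluster),
giving a tunable, analytically checkable Fst.  RIL meiosis uses Haldane's
map function (no interference); residual heterozygosity decays by half per
selfing generation and is retained, not forced to fixation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geno import GenotypeMatrix

logger = logging.getLogger("soygp")

PANEL_SIZES_FULL = {"A": 1007, "B": 607, "C": 965, "D": 811, "E": 508, "F": 243}
CLUSTERS = {"A": "I", "B": "I", "C": "I", "D": "I", "E": "II", "F": "II"}
#: parent trait means (oil %, protein %): JD12 high-protein, NF58 high-oil
PARENT_MEANS = {"P1": (17.0, 46.0), "P2": (24.0, 36.0)}
TRAITS = ("oil", "protein")


@dataclass
class SimPanelConfig:
    """Configuration for the structured germplasm-panel generator."""

    n_markers: int = 2000
    n_chromosomes: int = 20
    chrom_length_cM: float = 100.0
    panel_sizes: dict = field(default_factory=lambda: dict(PANEL_SIZES_FULL))
    cluster_assignment: dict = field(default_factory=lambda: dict(CLUSTERS))
    fst_within_cluster: float = 0.05
    fst_between_cluster: float = 0.30
    ld_block_size: int = 10
    ld_strength: float = 0.95
    size_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        fw, fb = self.fst_within_cluster, self.fst_between_cluster
        # fw < fb required except in the no-differentiation limit fw = fb = 0
        if not (0 <= fw <= fb < 1) or (fb > 0 and fw >= fb):
            raise ValueError("need 0 <= fst_within_cluster < fst_between_cluster < 1")
        if set(self.panel_sizes) != set(self.cluster_assignment):
            raise ValueError("panel_sizes and cluster_assignment labels differ")
        if any(self.scaled_size(k) < 2 for k in self.panel_sizes):
            raise ValueError("every scaled panel size must be >= 2")

    def scaled_size(self, label: str) -> int:
        return max(2, int(round(self.panel_sizes[label] * self.size_scale)))


@dataclass
class TraitArchitecture:
    """Genetic architecture of the two jointly simulated traits."""

    n_qtl: int = 200
    effect_correlation: float = -0.7
    target_h2: float = 0.9
    n_env: int = 6
    n_rep: int = 3
    gxe_variance_ratio: float = 0.2
    parent_means: dict = field(default_factory=lambda: dict(PARENT_MEANS))

    def __post_init__(self) -> None:
        if not -1 <= self.effect_correlation <= 1:
            raise ValueError("effect_correlation must be in [-1, 1]")
        if not 0 < self.target_h2 <= 1:
            raise ValueError("target_h2 must be in (0, 1]")


@dataclass
class RilConfig:
    """Bi-parental RIL population: F1 selfed to the final generation by SSD."""

    n_lines: int = 175
    final_generation: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if self.final_generation < 2:
            raise ValueError("final_generation must be >= 2")


# ---------------------------------------------------------------------------
# marker map


def make_marker_map(
    n_markers: int, n_chromosomes: int = 20, chrom_length_cM: float = 100.0
) -> pd.DataFrame:
    """Evenly spaced marker map: columns marker, chrom, pos (bp), cM."""
    per = np.full(n_chromosomes, n_markers // n_chromosomes)
    per[: n_markers % n_chromosomes] += 1
    rows = []
    k = 0
    for c in range(n_chromosomes):
        cm = np.linspace(0.0, chrom_length_cM, per[c], endpoint=False)
        for x in cm:
            rows.append((f"m{k:05d}", f"Gm{c + 1:02d}", int(round(x * 1e5)) + 1, x))
            k += 1
    return pd.DataFrame(rows, columns=["marker", "chrom", "pos", "cM"])


# ---------------------------------------------------------------------------
# founder panels (hierarchical Balding–Nichols)


def _ancestral_frequencies(blocks: np.ndarray,
                           rng: np.random.Generator) -> np.ndarray:
    """Blockwise ancestral frequencies: markers in one LD block share a
    base frequency with small jitter, as SNPs on a shared haplotype
    background do, which keeps within-block tagging strong."""
    base = rng.uniform(0.15, 0.85, size=int(blocks.max()) + 1)
    jitter = rng.normal(0.0, 0.05, size=blocks.size)
    return np.clip(base[blocks] + jitter, 0.05, 0.95)


def _bn_drift(p: np.ndarray, fst: float, rng: np.random.Generator) -> np.ndarray:
    """Draw drifted frequencies around p at differentiation fst."""
    if fst <= 0:
        return p.copy()
    # keep beta parameters strictly positive when a parent frequency has
    # drifted numerically to the boundary
    pc = np.clip(p, 1e-9, 1.0 - 1e-9)
    a = pc * (1.0 - fst) / fst
    b = (1.0 - pc) * (1.0 - fst) / fst
    return rng.beta(a, b)


def _flip_orientation(orient: np.ndarray, rate: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Flip each marker's LD phase with probability ``rate`` (drift proxy)."""
    if rate <= 0:
        return orient.copy()
    return np.where(rng.random(orient.shape) < rate, -orient, orient)


def block_index(n_markers: int, n_chromosomes: int, block_size: int) -> np.ndarray:
    """Consecutive-marker LD blocks within chromosomes (matches the map
    layout of make_marker_map)."""
    per = np.full(n_chromosomes, n_markers // n_chromosomes)
    per[: n_markers % n_chromosomes] += 1
    out = np.empty(n_markers, dtype=np.int64)
    k = b0 = 0
    for c in range(n_chromosomes):
        within = np.arange(per[c]) // max(block_size, 1)
        out[k:k + per[c]] = b0 + within
        b0 += int(within[-1]) + 1 if per[c] else 0
        k += per[c]
    return out


def draw_block_haplotypes(
    p: np.ndarray,
    orient: np.ndarray,
    blocks: np.ndarray,
    ld_strength: float,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """n haplotypes with block LD and exact marginal frequencies p.

    Each haplotype draws one latent uniform per block; a marker copies the
    block latent with probability ``ld_strength`` (else an independent
    uniform) and reads it through its orientation (u or 1−u), so markers
    sharing a block are correlated while every marker stays Bernoulli(p_j)
    marginally.  Orientation flips between populations reverse the phase
    of that correlation without touching allele frequencies.
    """
    m = p.size
    u = rng.random((n, int(blocks.max()) + 1))[:, blocks]
    u = np.where(orient > 0, u, 1.0 - u)
    mix = rng.random((n, m)) < ld_strength
    v = np.where(mix, u, rng.random((n, m)))
    return v < p


def _panel_profiles(config: SimPanelConfig):
    """Per-panel allele frequencies and LD orientations (deterministic).

    Runs on its own seed stream so callers (e.g. breeding-population
    parent construction) can regenerate profiles without re-simulating
    genotypes.
    """
    rng = np.random.default_rng([config.seed, 0])
    m = config.n_markers
    blocks = block_index(m, config.n_chromosomes, config.ld_block_size)
    p_anc = _ancestral_frequencies(blocks, rng)
    orient_anc = np.ones(m)
    clusters = sorted(set(config.cluster_assignment.values()))
    p_cluster, o_cluster = {}, {}
    for cl in clusters:
        p_cluster[cl] = _bn_drift(p_anc, config.fst_between_cluster, rng)
        o_cluster[cl] = _flip_orientation(
            orient_anc, config.fst_between_cluster, rng
        )
    freqs, orients = {}, {}
    for lab in sorted(config.panel_sizes):
        cl = config.cluster_assignment[lab]
        freqs[lab] = _bn_drift(p_cluster[cl], config.fst_within_cluster, rng)
        orients[lab] = _flip_orientation(
            o_cluster[cl], config.fst_within_cluster, rng
        )
    return freqs, orients, blocks


def panel_profile(config: SimPanelConfig, label: str):
    """Frequency/orientation/block profile of one panel (for e.g. drawing
    breeding-population parents from that panel's gene pool)."""
    freqs, orients, blocks = _panel_profiles(config)
    return freqs[label], orients[label], blocks


def simulate_founder_panels(config: SimPanelConfig):
    """Simulate the six-panel, two-cluster germplasm collection.

    Returns (GenotypeMatrix, panel labels as a pandas Series indexed by
    sample id, marker map DataFrame).  Allele frequencies drift
    hierarchically (Balding–Nichols at the cluster then panel level);
    genotypes are Hardy–Weinberg within panel, with block LD whose phase
    orientation itself drifts with divergence, so marker–QTL associations
    are consistent within a cluster but partly reversed across clusters.
    """
    freqs, orients, blk = _panel_profiles(config)
    rng = np.random.default_rng([config.seed, 1])
    m = config.n_markers
    blocks, sample_ids, panel_of = [], [], []
    for lab in sorted(config.panel_sizes):
        n = config.scaled_size(lab)
        h1 = draw_block_haplotypes(
            freqs[lab], orients[lab], blk, config.ld_strength, n, rng
        )
        h2 = draw_block_haplotypes(
            freqs[lab], orients[lab], blk, config.ld_strength, n, rng
        )
        blocks.append((h1.astype(np.float64) + h2))
        sample_ids.extend(f"{lab}{i:04d}" for i in range(n))
        panel_of.extend([lab] * n)
    X = np.vstack(blocks)
    mono = (X.std(axis=0) == 0).mean()
    if mono > 0.5:
        logger.warning("%.0f%% of simulated markers are monomorphic", 100 * mono)
    mmap = make_marker_map(m, config.n_chromosomes, config.chrom_length_cM)
    g = GenotypeMatrix(
        sample_ids=np.array(sample_ids, dtype=object),
        marker_ids=mmap["marker"].to_numpy(dtype=object),
        chrom=mmap["chrom"].to_numpy(dtype=object),
        pos=mmap["pos"].to_numpy(),
        dosage=X,
        coding="alt",
    )
    panels = pd.Series(panel_of, index=g.sample_ids, name="panel")
    return g, panels, mmap


def hudson_fst(g: GenotypeMatrix, groups: pd.Series, a: str, b: str) -> float:
    """Mean Hudson Fst between two groups over polymorphic markers.

    Per-marker Hudson estimator averaged as ratio-of-means:
    Fst = mean(num) / mean(den) with num = (p1−p2)² − p1q1/(n1−1) − p2q2/(n2−1),
    den = p1q2 + p2q1.  Used as the independent check that the generator
    realizes its requested differentiation.
    """
    ia = groups.index[groups == a]
    ib = groups.index[groups == b]
    Xa = g.dosage[g.sample_index(ia)]
    Xb = g.dosage[g.sample_index(ib)]
    n1, n2 = Xa.shape[0], Xb.shape[0]
    p1, p2 = Xa.mean(0) / 2, Xb.mean(0) / 2
    q1, q2 = 1 - p1, 1 - p2
    num = (p1 - p2) ** 2 - p1 * q1 / (2 * n1 - 1) - p2 * q2 / (2 * n2 - 1)
    den = p1 * q2 + p2 * q1
    ok = den > 0
    return float(num[ok].mean() / den[ok].mean())


def simulate_divergence_gradient(
    n_markers: int,
    panel_size: int,
    fst_levels,
    n_test: int,
    seed: int,
    n_chromosomes: int = 20,
):
    """Training panels at graded divergence from one test population.

    The test population ("BP") is drawn essentially at the ancestral
    frequencies; each training panel P1, P2, ... drifts from that ancestor
    at its own Fst level.  Used to study how prediction ability decays
    with genetic distance between training and test sets.

    Returns (GenotypeMatrix, panel labels Series, marker map).
    """
    rng = np.random.default_rng(seed)
    blk = block_index(n_markers, n_chromosomes, 10)
    p_anc = _ancestral_frequencies(blk, rng)
    orient_anc = np.ones(n_markers)

    def draw_panel(p, orient, n):
        h1 = draw_block_haplotypes(p, orient, blk, 0.95, n, rng)
        h2 = draw_block_haplotypes(p, orient, blk, 0.95, n, rng)
        return h1.astype(np.float64) + h2

    blocks = [draw_panel(p_anc, orient_anc, n_test)]
    sample_ids = [f"BP{i:04d}" for i in range(n_test)]
    panel_of = ["BP"] * n_test
    for k, fst in enumerate(fst_levels, start=1):
        p_k = _bn_drift(p_anc, float(fst), rng)
        o_k = _flip_orientation(orient_anc, float(fst), rng)
        blocks.append(draw_panel(p_k, o_k, panel_size))
        sample_ids.extend(f"P{k}_{i:04d}" for i in range(panel_size))
        panel_of.extend([f"P{k}"] * panel_size)
    mmap = make_marker_map(n_markers, n_chromosomes)
    g = GenotypeMatrix(
        sample_ids=np.array(sample_ids, dtype=object),
        marker_ids=mmap["marker"].to_numpy(dtype=object),
        chrom=mmap["chrom"].to_numpy(dtype=object),
        pos=mmap["pos"].to_numpy(),
        dosage=np.vstack(blocks),
        coding="alt",
    )
    return g, pd.Series(panel_of, index=g.sample_ids, name="panel"), mmap


# ---------------------------------------------------------------------------
# bi-parental RILs


def make_inbred_parents(
    p: np.ndarray,
    rng: np.random.Generator,
    orient: np.ndarray | None = None,
    blocks: np.ndarray | None = None,
    ld_strength: float = 0.9,
):
    """Two fully inbred parents drawn from allele-frequency profile p.

    Returns (hap1_pair, hap2_pair) as (2, m) 0/1 arrays with identical
    rows.  When an LD profile (orientation + blocks) is supplied — e.g.
    from panel_profile — the parental haplotypes carry that population's
    block LD, so the derived RILs share its marker–QTL phase.  Markers
    where the draws coincide stay monomorphic in the cross, as in a real
    bi-parental population.
    """
    if orient is None:
        h1 = (rng.random(p.shape) < p).astype(np.int8)
        h2 = (rng.random(p.shape) < p).astype(np.int8)
    else:
        h1 = draw_block_haplotypes(p, orient, blocks, ld_strength, 1, rng)[0]
        h2 = draw_block_haplotypes(p, orient, blocks, ld_strength, 1, rng)[0]
        h1, h2 = h1.astype(np.int8), h2.astype(np.int8)
    return np.vstack([h1, h1]), np.vstack([h2, h2])


def _meiosis(hap_pair: np.ndarray, rec: np.ndarray, chrom_start: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """One gamete from a diploid: Haldane recombination, free chromosome starts.

    rec[j] = recombination probability between markers j-1 and j within a
    chromosome; chrom_start marks the first marker of each chromosome,
    where the source chromatid is redrawn at random.
    """
    m = rec.shape[0]
    switch = rng.random(m) < rec
    switch[chrom_start] = False
    start = (rng.random(m) < 0.5).astype(np.int64)
    # chromatid = (fair start bit of the chromosome + #switches since its
    # first marker) mod 2 — the crossover process with no interference
    cs = np.cumsum(switch)
    start_pos = np.maximum.accumulate(
        np.where(chrom_start, np.arange(m), 0)
    )
    src = (start[start_pos] + cs - cs[start_pos]) % 2
    return np.where(src == 0, hap_pair[0], hap_pair[1]).astype(np.int8)


def _recomb_probs(marker_map: pd.DataFrame):
    """Haldane recombination fractions between adjacent markers."""
    cm = marker_map["cM"].to_numpy(float)
    chrom = marker_map["chrom"].to_numpy()
    d = np.diff(cm, prepend=cm[0])
    if np.any(d[1:][chrom[1:] == chrom[:-1]] < 0):
        raise ValueError("marker map not sorted within chromosome")
    rec = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    chrom_start = np.r_[True, chrom[1:] != chrom[:-1]]
    rec[chrom_start] = 0.5  # unlinked across chromosomes
    return rec, chrom_start


def simulate_biparental_rils(
    parent1: np.ndarray,
    parent2: np.ndarray,
    marker_map: pd.DataFrame,
    config: RilConfig,
) -> GenotypeMatrix:
    """F1 of two inbred parents selfed to F_{final_generation} by SSD.

    Each line keeps a single offspring per selfing round (single seed
    descent): final_generation − 1 rounds of selfing after the F1.  Dosage
    counts copies of allele 1 (the same physical allele the founder panels
    count), so RILs merge directly with panel genotypes; markers where the
    parents share an allele are uniform across lines.
    """
    parent1 = np.asarray(parent1, dtype=np.int8)
    parent2 = np.asarray(parent2, dtype=np.int8)
    for par, name in ((parent1, "parent1"), (parent2, "parent2")):
        if par.shape[0] != 2 or not np.array_equal(par[0], par[1]):
            raise ValueError(f"{name} must be a homozygous (2, m) haplotype pair")
    rng = np.random.default_rng(config.seed)
    rec, chrom_start = _recomb_probs(marker_map)
    m = parent1.shape[1]
    lines = np.empty((config.n_lines, m), dtype=float)
    for i in range(config.n_lines):
        ind = (parent1[0].copy(), parent2[0].copy())  # the F1
        for _ in range(config.final_generation - 1):
            g1 = _meiosis(np.vstack(ind), rec, chrom_start, rng)
            g2 = _meiosis(np.vstack(ind), rec, chrom_start, rng)
            ind = (g1, g2)
        lines[i] = ind[0].astype(np.float64) + ind[1]  # copies of allele 1
    return GenotypeMatrix(
        sample_ids=np.array(
            [f"RIL{i:04d}" for i in range(config.n_lines)], dtype=object
        ),
        marker_ids=marker_map["marker"].to_numpy(dtype=object),
        chrom=marker_map["chrom"].to_numpy(dtype=object),
        pos=marker_map["pos"].to_numpy(),
        dosage=lines,
        coding="alt",
    )


# ---------------------------------------------------------------------------
# trait architecture and phenotypes


def assign_qtl_effects(
    g: GenotypeMatrix, arch: TraitArchitecture, seed: int
) -> np.ndarray:
    """Per-marker effect pairs (m, 2) for the two traits.

    n_qtl markers are chosen uniformly without replacement; their effect
    pairs come from a standard bivariate normal with correlation
    ``effect_correlation``; all other markers get exactly zero effects.
    """
    if arch.n_qtl > g.n_markers:
        raise ValueError("n_qtl exceeds number of markers")
    rng = np.random.default_rng(seed)
    qtl = rng.choice(g.n_markers, size=arch.n_qtl, replace=False)
    rho = arch.effect_correlation
    e1 = rng.standard_normal(arch.n_qtl)
    z = rng.standard_normal(arch.n_qtl)
    e2 = rho * e1 + np.sqrt(max(0.0, 1.0 - rho**2)) * z
    effects = np.zeros((g.n_markers, 2))
    effects[qtl, 0] = e1
    effects[qtl, 1] = e2
    return effects


def simulate_phenotypes(
    g: GenotypeMatrix,
    effects: np.ndarray,
    arch: TraitArchitecture,
    seed: int,
):
    """Multi-environment replicated phenotypes for both traits.

    Model per trait: Y_ijk = μ + E_i + R_j(E_i) + G_k + GE_ik + ε_ijk with
    independent normal environment, replicate-within-environment, G×E and
    residual effects.  σ²_GE = gxe_variance_ratio · σ²_G, and the residual
    variance is solved from the line-mean broad-sense heritability
    h² = σ²G / (σ²G + σ²GE/e + σ²ε/(r·e)) so the realized ANOVA estimate
    lands near ``target_h2``.  Trait means are anchored midway between the
    two parents' published means (cosmetic shift only).

    Returns (PhenotypeTable DataFrame with columns line/env/rep/trait/value,
    truth dict with genetic values and variance components).
    """
    if effects.shape != (g.n_markers, 2):
        raise ValueError("effects must be (n_markers, 2)")
    rng = np.random.default_rng(seed)
    e, r = arch.n_env, arch.n_rep
    gvals = g.dosage @ effects  # (n, 2)
    truth = {"h2_target": arch.target_h2, "traits": {}}
    frames = []
    for t, trait in enumerate(TRAITS):
        gk = gvals[:, t]
        s2G = float(np.var(gk, ddof=1))
        if s2G == 0:
            raise ValueError("zero genetic variance: cannot scale to target_h2")
        s2GE = arch.gxe_variance_ratio * s2G
        s2e = r * e * (s2G / arch.target_h2 - s2G - s2GE / e)
        if s2e < 0:
            raise ValueError(
                "target_h2 unreachable with this gxe_variance_ratio/n_env"
            )
        mu = float(np.mean([pm[t] for pm in arch.parent_means.values()]))
        gk_c = gk - gk.mean()
        env_eff = rng.normal(0.0, np.sqrt(s2G), size=e)
        rep_eff = rng.normal(0.0, np.sqrt(0.25 * s2G), size=(e, r))
        ge = rng.normal(0.0, np.sqrt(s2GE), size=(g.n_samples, e))
        eps = rng.normal(0.0, np.sqrt(s2e), size=(g.n_samples, e, r))
        n = g.n_samples
        y = (
            mu
            + gk_c[:, None, None]
            + env_eff[None, :, None]
            + rep_eff[None, :, :]
            + ge[:, :, None]
            + eps
        )
        idx = pd.MultiIndex.from_product(
            [g.sample_ids, [f"E{i + 1}" for i in range(e)],
             [f"R{j + 1}" for j in range(r)]],
            names=["line", "env", "rep"],
        )
        df = pd.DataFrame({"value": y.reshape(n * e * r)}, index=idx).reset_index()
        df["trait"] = trait
        frames.append(df[["line", "env", "rep", "trait", "value"]])
        truth["traits"][trait] = {
            "mu": mu,
            "sigma2_G": s2G,
            "sigma2_GE": s2GE,
            "sigma2_e": s2e,
            "genetic_values": dict(zip(map(str, g.sample_ids), (mu + gk_c).tolist())),
        }
    truth["qtl_indices"] = np.nonzero(effects.any(axis=1))[0].tolist()
    return pd.concat(frames, ignore_index=True), truth


def inject_missing(g: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Mask each dosage cell independently with probability ``rate``."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0:
        return g
    rng = np.random.default_rng(seed)
    mask = rng.random(g.dosage.shape) < rate
    X = g.dosage.copy()
    X[mask] = np.nan
    from dataclasses import replace

    return replace(g, dosage=X, missing_mask=mask)
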