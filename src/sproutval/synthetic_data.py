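"""Synthetic genotype panels and germination trials with known ground truth.

The generator emulates the structure of a candidate-marker validation
study on an inbred cultivar panel: 200 genotypes scored in 4
environments x 2 replicates with 40-seed germination tests, genotyped
with a ~38-marker KASP panel carrying a realistic contamination profile
(a block of assays with very high missing-call rates, two with gross
excess heterozygosity, several monomorphic assays, one at minor allele
frequency 2%, and two complete-LD marker pairs, one of them designed on
the complementary DNA strand).  One large-effect dormancy locus
(tolerant-allele frequency 0.58, effect -0.14 GI) and several
small-effect loci enter the latent genotype value additively on top of
a polygenic term; environment, replicate-within-environment, GxE and
residual effects are drawn from the variance components of the
across-environment model, with the polygenic variance set so the total
genotypic variance matches its target (0.031 GI^2 by default, against
0.015 environmental, 0.018 GxE and 0.003 residual).

Germination counts are binomial given the latent plot mean m (truncated
to [0.02, 0.98]): day-3 and day-6 cohort probabilities are equal
(pi6 = pi3) and pi3 is chosen so the expected germination index equals
m, i.e. pi3 solves m = pi3 * (3 - pi3) / 2.  An optional beta-binomial
switch adds overdispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sproutval.marker_qc import COMPLEMENT
from sproutval.phenotype import PlotGermination


@dataclass(frozen=True)
class MarkerSpec:
    """Generating specification for one marker.

    ``freq_tolerant`` is the population frequency of the (homozygous)
    tolerant allele; 0 or 1 makes the marker monomorphic.  ``effect`` is
    the tolerant-vs-susceptible shift of the latent GI in GI units
    (negative = dormancy-increasing).  ``ld_partner`` copies the
    partner's allele partition (complete LD), so LD partners should
    carry effect 0 to avoid double-counting the shared locus.
    ``strand_complement`` emits the assay on the complementary strand.
    """

    marker_id: str
    chromosome: str = "1A"
    allele_tolerant: str = "G"
    allele_susceptible: str = "A"
    freq_tolerant: float = 0.5
    effect: float = 0.0
    missing_rate: float = 0.0
    het_rate: float = 0.0
    ld_partner: str | None = None
    strand_complement: bool = False

    def __post_init__(self):
        for name in ("freq_tolerant", "missing_rate", "het_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.marker_id}: {name}={v} outside [0,1]")


def default_marker_panel() -> list[MarkerSpec]:
    """38-marker panel mirroring a realistic KASP validation assay.

    22 clean polymorphic markers (9 with planted effects, of which two
    pairs are in complete LD; 13 null), 6 with 70-95% missing calls, 2
    with gross heterozygosity, 7 monomorphic and 1 at MAF 0.02.
    """
    panel = [
        # large-effect dormancy locus and its linked neighbour
        MarkerSpec("TaMKK3-A", "4A", "G", "T", 0.58, -0.14,
                   missing_rate=0.02, het_rate=0.005),
        MarkerSpec("wsnp_Ex_rep_c66324_64493429", "4A", "T", "C", 0.39, -0.10,
                   missing_rate=0.03, het_rate=0.005),
        # coding-region pair in complete LD; the second assay reads the
        # complementary strand
        MarkerSpec("TaPHS1-646", "3A", "G", "A", 0.80, -0.08,
                   missing_rate=0.02, het_rate=0.0),
        MarkerSpec("TaPHS1-666", "3A", "A", "T", 0.80, 0.0,
                   ld_partner="TaPHS1-646", strand_complement=True,
                   missing_rate=0.04, het_rate=0.0),
        # second complete-LD pair
        MarkerSpec("IAAV615", "4A", "A", "G", 0.20, -0.08,
                   missing_rate=0.02, het_rate=0.01),
        MarkerSpec("BS00037019_51", "4A", "T", "C", 0.20, 0.0,
                   ld_partner="IAAV615", missing_rate=0.05, het_rate=0.0),
        # further small-effect loci
        MarkerSpec("KASP765", "3B", "A", "G", 0.22, -0.08,
                   missing_rate=0.03, het_rate=0.01),
        MarkerSpec("BS00072025_51", "4A", "G", "A", 0.31, -0.07,
                   missing_rate=0.02, het_rate=0.0),
        MarkerSpec("wsnp_Ex_c908_1754208", "7B", "C", "T", 0.30, -0.07,
                   missing_rate=0.04, het_rate=0.005),
    ]
    # null polymorphic markers to fill the clean set to 22
    null_freqs = [0.43, 0.12, 0.25, 0.35, 0.18, 0.45, 0.08, 0.28,
                  0.15, 0.38, 0.22, 0.33, 0.10]
    for i, f in enumerate(null_freqs, start=1):
        panel.append(MarkerSpec(f"NULL_{i:02d}", "5A", "C", "T", f, 0.0,
                                missing_rate=0.05, het_rate=0.01))
    # contamination block: six assays with extreme missing-call rates
    for i, miss in enumerate([0.95, 0.90, 0.85, 0.80, 0.75, 0.705], start=1):
        panel.append(MarkerSpec(f"FAIL_MISS_{i}", "2B", "A", "C", 0.4, 0.0,
                                missing_rate=miss, het_rate=0.0))
    # two assays with gross excess heterozygosity
    panel.append(MarkerSpec("FAIL_HET_1", "7A", "G", "T", 0.5, 0.0,
                            missing_rate=0.0, het_rate=0.325))
    panel.append(MarkerSpec("FAIL_HET_2", "7A", "A", "G", 0.5, 0.0,
                            missing_rate=0.0, het_rate=0.655))
    # seven monomorphic assays
    for i in range(1, 8):
        panel.append(MarkerSpec(f"MONO_{i}", "5B", "T", "C", 0.0, 0.0,
                                missing_rate=0.02, het_rate=0.0))
    # one marker below the MAF floor
    panel.append(MarkerSpec("RARE_1", "2A", "A", "G", 0.02, 0.0,
                            missing_rate=0.01, het_rate=0.0))
    return panel


def _marker_genetic_variance(markers: list[MarkerSpec]) -> float:
    """Genotypic variance contributed by planted marker effects.

    For a homozygous 0/1 locus at tolerant frequency p the contribution
    is p(1-p) * effect^2; complete-LD partners share a locus and carry
    effect 0 by convention.
    """
    return sum(m.freq_tolerant * (1 - m.freq_tolerant) * m.effect ** 2
               for m in markers)


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and generating parameters.

    Defaults reproduce the reference design: 200 genotypes, 4
    environments, 2 replicates, 40 seeds per germination test, grand
    mean GI 0.35, total genotypic variance 0.031, environment 0.015,
    GxE 0.018, residual 0.003 (GI^2 units), replicate-within-environment
    0.001 (small block variance typical of well-managed trials).  The
    polygenic variance is the genotypic target minus the variance of the
    planted marker effects.
    """

    n_genotypes: int = 200
    n_environments: int = 4
    n_replicates: int = 2
    seeds_per_test: int = 40
    mu: float = 0.35
    sigma2_g_total: float = 0.031
    sigma2_e: float = 0.015
    sigma2_gxe: float = 0.018
    sigma2_rep: float = 0.001
    sigma2_eps: float = 0.003
    markers: tuple[MarkerSpec, ...] = field(
        default_factory=lambda: tuple(default_marker_panel()))
    env_means: tuple[float, ...] | None = None  # fixed env means override
    overdispersion: float = 0.0  # beta-binomial switch; 0 = binomial
    exact_counts: bool = False   # realize marker rates as exact counts
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("sigma2_g_total", "sigma2_e", "sigma2_gxe",
                     "sigma2_rep", "sigma2_eps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.seeds_per_test < 1 or self.n_genotypes < 1:
            raise ValueError("design counts must be >= 1")
        ids = [m.marker_id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate marker ids in panel")
        for m in self.markers:
            if m.ld_partner is not None and m.ld_partner not in ids:
                raise ValueError(
                    f"{m.marker_id}: LD partner {m.ld_partner} not in panel")

    @property
    def sigma2_g_polygenic(self) -> float:
        return max(self.sigma2_g_total - _marker_genetic_variance(list(self.markers)), 0.0)


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery checks."""

    genetic_values: pd.Series          # per-genotype latent value (markers + polygenic)
    marker_effects: dict[str, float]   # per-marker true effect (GI units)
    tolerant_states: pd.DataFrame      # genotype x marker 0/1 tolerant indicator
    polygenic_values: pd.Series
    components: dict[str, float]       # generating variance components
    # sample variances of the effects actually drawn by simulate_trials;
    # with few environments these scatter widely around the generating
    # values and are the estimable recovery target
    realized_components: dict[str, float] | None = None


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.rng_seed, spawn_key=(stage,)))


def simulate_panel(config: SimulationConfig):
    """Draw the genotype call matrix, marker metadata and ground truth.

    Returns ``(matrix, meta, truth)``: a genotypes x markers DataFrame
    of diploid string calls (NA for missing), the marker metadata table,
    and a :class:`GroundTruth`.
    """
    rng = _rng(config, 0)
    n = config.n_genotypes
    gids = [f"G{i + 1:03d}" for i in range(n)]
    markers = list(config.markers)
    by_id = {m.marker_id: m for m in markers}

    # tolerant-state draws; LD partners copy the partner's partition
    states: dict[str, np.ndarray] = {}

    def _draw_states(freq: float) -> np.ndarray:
        if config.exact_counts:
            # exact composition: round(freq*n) tolerant calls at seeded positions
            s = np.zeros(n, dtype=int)
            s[: round(freq * n)] = 1
            return rng.permutation(s)
        return (rng.random(n) < freq).astype(int)

    def _mask(rate: float) -> np.ndarray:
        if config.exact_counts:
            m_ = np.zeros(n, dtype=bool)
            m_[: round(rate * n)] = True
            return rng.permutation(m_)
        return rng.random(n) < rate

    def state_of(m: MarkerSpec) -> np.ndarray:
        if m.marker_id in states:
            return states[m.marker_id]
        if m.ld_partner is not None:
            s = state_of(by_id[m.ld_partner])
        else:
            s = _draw_states(m.freq_tolerant)
        states[m.marker_id] = s
        return s

    # draw independent loci in panel order for reproducibility
    for m in markers:
        if m.ld_partner is None:
            state_of(m)
    for m in markers:
        state_of(m)

    calls = {}
    meta_rows = []
    for m in markers:
        s = states[m.marker_id]
        tol, sus = m.allele_tolerant, m.allele_susceptible
        if m.strand_complement:
            tol_e, sus_e = COMPLEMENT[tol], COMPLEMENT[sus]
        else:
            tol_e, sus_e = tol, sus
        col = np.where(s == 1, tol_e * 2, sus_e * 2).astype(object)
        het = _mask(m.het_rate)
        col[het] = tol_e + sus_e
        miss = _mask(m.missing_rate)
        col[miss] = None
        calls[m.marker_id] = col
        meta_rows.append({
            "marker_id": m.marker_id,
            "chromosome": m.chromosome,
            "allele1": tol_e,
            "allele2": sus_e,
            "strand_complement": m.strand_complement,
            "tolerant_allele": tol,   # on the expected strand
        })
    matrix = pd.DataFrame(calls, index=pd.Index(gids, name="genotype_id"))
    matrix = matrix.astype("string")
    meta = pd.DataFrame(meta_rows)

    tolerant = pd.DataFrame({m.marker_id: states[m.marker_id] for m in markers},
                            index=matrix.index)
    # centre marker contributions on their population mean so that the
    # grand mean of the latent GI stays at mu
    marker_part = sum((states[m.marker_id] - m.freq_tolerant) * m.effect
                      for m in markers)
    poly = rng.normal(0.0, np.sqrt(config.sigma2_g_polygenic), n)
    genetic = pd.Series(marker_part + poly, index=matrix.index, name="genetic_value")
    truth = GroundTruth(
        genetic_values=genetic,
        marker_effects={m.marker_id: m.effect for m in markers},
        tolerant_states=tolerant,
        polygenic_values=pd.Series(poly, index=matrix.index),
        components={
            "sigma2_g": config.sigma2_g_total,
            "sigma2_e": config.sigma2_e,
            "sigma2_gxe": config.sigma2_gxe,
            "sigma2_rep": config.sigma2_rep,
            "sigma2_eps": config.sigma2_eps,
        },
    )
    return matrix, meta, truth


def pi3_for_mean(m):
    """Day-3 cohort probability giving expected GI m under pi6 = pi3.

    Solves m = pi3 * (3 - pi3) / 2 on [0, 1]:
    pi3 = (3 - sqrt(9 - 8 m)) / 2.
    """
    m = np.asarray(m, dtype=float)
    return (3.0 - np.sqrt(9.0 - 8.0 * m)) / 2.0


def simulate_trials(config: SimulationConfig, truth: GroundTruth) -> list[PlotGermination]:
    """Draw plot-level germination counts for the multi-environment trial.

    The latent plot mean is ``mu + genetic_i + e_j + (gxe)_ij + r_k(j) +
    eps_ijk`` truncated to [0.02, 0.98]; counts are n3 ~ Bin(N, pi3) and
    n6 ~ Bin(N - n3, pi3) with pi3 from :func:`pi3_for_mean`.
    """
    rng = _rng(config, 1)
    n, ne, nr = config.n_genotypes, config.n_environments, config.n_replicates
    N = config.seeds_per_test
    gids = list(truth.genetic_values.index)
    envs = [f"E{j + 1}" for j in range(ne)]

    if config.env_means is not None:
        if len(config.env_means) != ne:
            raise ValueError("env_means length must equal n_environments")
        e_eff = np.asarray(config.env_means, dtype=float) - config.mu
    else:
        e_eff = rng.normal(0.0, np.sqrt(config.sigma2_e), ne)
    r_eff = rng.normal(0.0, np.sqrt(config.sigma2_rep), (ne, nr))
    ge_eff = rng.normal(0.0, np.sqrt(config.sigma2_gxe), (n, ne))
    eps = rng.normal(0.0, np.sqrt(config.sigma2_eps), (n, ne, nr))

    g = truth.genetic_values.to_numpy()
    truth.realized_components = {
        "sigma2_g": float(np.var(g, ddof=1)),
        "sigma2_e": float(np.var(e_eff, ddof=1)) if ne > 1 else 0.0,
        "sigma2_gxe": float(np.var(ge_eff, ddof=1)),
        "sigma2_rep": float(np.var(r_eff, ddof=1)),
        "sigma2_eps": float(np.var(eps, ddof=1)),
    }
    m = (config.mu + g[:, None, None] + e_eff[None, :, None]
         + ge_eff[:, :, None] + r_eff[None, :, :] + eps)
    m = np.clip(m, 0.02, 0.98)
    p3 = pi3_for_mean(m)
    if config.overdispersion > 0:
        # beta-binomial: plot-level cohort probability jittered around p3
        conc = 1.0 / config.overdispersion
        a = np.clip(p3 * conc, 1e-6, None)
        b = np.clip((1.0 - p3) * conc, 1e-6, None)
        p3 = rng.beta(a, b)
    n3 = rng.binomial(N, p3)
    n6 = rng.binomial(N - n3, p3)

    plots = []
    for i, gid in enumerate(gids):
        for j, env in enumerate(envs):
            for k in range(nr):
                plots.append(PlotGermination(
                    genotype_id=gid, environment_id=env, replicate=k + 1,
                    n3=int(n3[i, j, k]), n6=int(n6[i, j, k]), N=N))
    return plots


def simulate_dataset(config: SimulationConfig):
    """Convenience wrapper: panel + trials in one call.

    Returns ``(matrix, meta, truth, plots)``.
    """
    matrix, meta, truth = simulate_panel(config)
    plots = simulate_trials(config, truth)
    return matrix, meta, truth, plots
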