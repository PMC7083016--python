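"""Synthetic study generator: genes, zero-inflated NB taxa, dichotomous outcome.

The generator emulates a two-group (e.g. healthy/diseased) study in which
some microbial taxa mediate the effect of host gene expression on the
outcome.  Genes are normal with two variance blocks (sd 0.5 for the first
half, 2.0 for the second).  Taxa are negative-binomial counts with excess
zeros; relationship blocks wire gene blocks, taxon blocks and the outcome
together:

=====  ======================  =======================================
block  relationships           role
=====  ======================  =======================================
1      gamma', alpha, beta2    true mediators of the low-variance genes
2      gamma', alpha           gene-linked, no unique outcome signal
3      gamma', beta2           outcome-linked, no gene link
4      gamma'                  null taxa
5..8   mirror of 1..4          for the high-variance gene half
=====  ======================  =======================================

Only blocks with all of gamma' (gene group shift), alpha (gene -> taxon
link) and beta2 (taxon -> outcome link) are true mediators.  At the
default 300 genes x 300 taxa the blocks are taxa 1-10 / 11-20 / 21-30 /
31-150 and their mirrors; at other sizes the same proportions are kept by
largest-remainder allocation.

Signal strength is the standardized group mean difference delta/sigma,
applied to gamma'-bearing genes (per-gene sigma) and, on the log scale,
to beta2-bearing taxa.  Overdispersion follows kappa = c/lambda + 1,
i.e. variance = lambda + c, so larger c means more dispersion.  Excess
zeros are imposed with per-taxon probabilities weighted by the log ratio
of taxon abundance to the population mean, globally rescaled so the
marginal zero fraction matches the requested level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "ScenarioSpec",
    "SyntheticDataset",
    "allocate_blocks",
    "simulate_genes",
    "simulate_taxa",
    "simulate_dataset",
    "build_scenario",
]

# block layout at reference scale (300 genes, 300 taxa)
GENE_BLOCK_WEIGHTS = (20, 130, 20, 130)
GENE_BLOCK_SIGMA = (0.5, 0.5, 2.0, 2.0)
GENE_BLOCK_GAMMA = (True, False, True, False)

TAXON_BLOCK_WEIGHTS = (10, 10, 10, 120, 10, 10, 10, 120)
# (alpha, beta2) flags per taxon block; gamma' is carried by the gene side
TAXON_BLOCK_FLAGS = (
    (True, True),
    (True, False),
    (False, True),
    (False, False),
    (True, True),
    (True, False),
    (False, True),
    (False, False),
)
# which gene block an alpha-linked taxon block reads from
TAXON_BLOCK_GENE_PARTNER = (0, 0, None, None, 2, 2, None, None)
TRUE_MEDIATOR_BLOCKS = (0, 4)


def allocate_blocks(n: int, weights: tuple[int, ...]) -> list[int]:
    """Largest-remainder allocation of n items proportional to weights.

    Deterministic: ties go to the lower block index.  Preserves the
    reference block proportions at any scale.
    """
    w = np.asarray(weights, float)
    exact = n * w / w.sum()
    sizes = np.floor(exact).astype(int)
    rem = exact - sizes
    short = n - sizes.sum()
    order = np.lexsort((np.arange(len(w)), -rem))
    for i in order[:short]:
        sizes[i] += 1
    return sizes.tolist()


def _block_slices(sizes: list[int]) -> list[slice]:
    edges = np.concatenate([[0], np.cumsum(sizes)])
    return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one simulation scenario.

    ``signal_strength`` is delta/sigma, the standardized group mean
    difference; ``zero_level`` the target marginal excess-zero proportion;
    ``dispersion_c`` the overdispersion constant c (variance = mean + c
    under the default parameterisation, so c = 1000 is high dispersion).
    """

    n_per_group: int = 40
    n_genes: int = 300
    n_taxa: int = 300
    signal_strength: float = 0.5
    zero_level: float = 0.8
    dispersion_c: float = 100.0
    dispersion_form: Literal["c_over_lambda", "kappa_linear"] = "c_over_lambda"
    abundance_meanlog: float = 3.0
    abundance_sdlog: float = 1.0
    alpha_link: float = 1.0
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.signal_strength <= 1) and self.signal_strength != 0:
            raise ValueError("signal_strength must lie in (0, 1] (or 0 for a null)")
        if not (0 <= self.zero_level < 1):
            raise ValueError("zero_level must lie in [0, 1)")
        if self.dispersion_c <= 0:
            raise ValueError("dispersion_c must be positive")

    @property
    def gene_blocks(self) -> list[slice]:
        return _block_slices(allocate_blocks(self.n_genes, GENE_BLOCK_WEIGHTS))

    @property
    def taxon_blocks(self) -> list[slice]:
        return _block_slices(allocate_blocks(self.n_taxa, TAXON_BLOCK_WEIGHTS))


@dataclass
class SyntheticDataset:
    """One simulated study with its ground truth."""

    genes: np.ndarray  # (n, n_genes) continuous
    taxa: np.ndarray  # (n, n_taxa) nonnegative integer counts
    outcome: np.ndarray  # (n,) binary group labels
    truth: np.ndarray  # (n_taxa,) bool, True for real mediators
    true_gene_sets: dict = field(default_factory=dict)  # taxon idx -> gene indices
    spec: ScenarioSpec | None = None

    @property
    def gene_names(self) -> list[str]:
        return [f"gene_{i + 1}" for i in range(self.genes.shape[1])]

    @property
    def taxon_names(self) -> list[str]:
        return [f"taxon_{j + 1}" for j in range(self.taxa.shape[1])]


def simulate_genes(
    spec: ScenarioSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the expression matrix and balanced group labels.

    Genes in gamma'-bearing blocks get a between-group mean shift of
    delta = signal_strength * sigma (per-gene sigma).
    """
    n = 2 * spec.n_per_group
    y = np.repeat([0, 1], spec.n_per_group)
    x = np.empty((n, spec.n_genes))
    for blk, sl in enumerate(spec.gene_blocks):
        size = sl.stop - sl.start
        if size == 0:
            continue
        sigma = GENE_BLOCK_SIGMA[blk]
        x[:, sl] = rng.normal(0.0, sigma, size=(n, size))
        if GENE_BLOCK_GAMMA[blk]:
            x[y == 1, sl] += spec.signal_strength * sigma
    return x, y


def _nb_params(mu: np.ndarray, spec: ScenarioSpec) -> tuple[np.ndarray, np.ndarray]:
    """Negative-binomial (r, p) for mean mu under the chosen dispersion form."""
    if spec.dispersion_form == "c_over_lambda":
        # kappa = c/lambda + 1  ->  var = mu + c
        r = mu**2 / spec.dispersion_c
    else:
        # literal kappa = c*lambda + 1 -> var = kappa*mu = mu + c*mu^2
        r = np.full_like(mu, 1.0 / spec.dispersion_c)
    r = np.maximum(r, 1e-8)
    p = r / (r + mu)
    return r, p


def simulate_taxa(
    genes: np.ndarray, outcome: np.ndarray, spec: ScenarioSpec, rng: np.random.Generator
) -> np.ndarray:
    """Draw the zero-inflated negative-binomial count table.

    Per taxon j the log mean is log(lambda_j) from a log-normal abundance
    profile, plus ``alpha_link`` times the standardized partner-gene-block
    mean for alpha-linked taxa, plus a group shift of
    signal_strength * abundance_sdlog for beta2-linked taxa.  Counts are
    NB with the spec's dispersion; excess zeros are then imposed with
    per-taxon probabilities weighted by max(0, log(lambda_j / mean
    lambda)) and globally rescaled (bisection) so the realized marginal
    zero fraction matches ``zero_level``.
    """
    n = genes.shape[0]
    j_total = spec.n_taxa
    lam = rng.lognormal(spec.abundance_meanlog, spec.abundance_sdlog, size=j_total)
    log_mu = np.tile(np.log(lam), (n, 1))
    for blk, sl in enumerate(spec.taxon_blocks):
        if sl.stop == sl.start:
            continue
        has_alpha, has_beta2 = TAXON_BLOCK_FLAGS[blk]
        if has_alpha:
            gsl = spec.gene_blocks[TAXON_BLOCK_GENE_PARTNER[blk]]
            score = genes[:, gsl].mean(axis=1)
            sd = score.std()
            if sd > 0:
                score = (score - score.mean()) / sd
            log_mu[:, sl] += spec.alpha_link * score[:, None]
        if has_beta2:
            shift = spec.signal_strength * spec.abundance_sdlog
            log_mu[outcome == 1, sl] += shift
    mu = np.exp(np.clip(log_mu, -20.0, 20.0))
    r, p = _nb_params(mu, spec)
    counts = rng.negative_binomial(r, p).astype(np.int64)

    # excess zeros: weights from the log ratio of abundance to the population
    # mean, rescaled to the target marginal level.  Below-mean taxa are zeroed
    # preferentially (detection-limit behaviour); weights are bounded
    # (relative range [1, 3], per-taxon cap 0.95) so no taxon is erased
    # outright.
    z_nb = (counts == 0).mean(axis=0)
    u = np.maximum(0.0, np.log(lam.mean() / lam))
    v = 1.0 + (2.0 * u / u.max() if u.max() > 0 else 0.0)
    pi_cap = 0.95

    def marginal(t: float) -> float:
        pi = np.clip(t * v, 0.0, pi_cap)
        return float(np.mean(pi + (1 - pi) * z_nb))

    if marginal(0.0) >= spec.zero_level:
        import warnings

        if spec.zero_level > 0 and marginal(0.0) > spec.zero_level + 1e-9:
            warnings.warn(
                "structural NB zeros already exceed the requested zero level; "
                "no excess zeros added",
                stacklevel=2,
            )
        t = 0.0
    elif marginal(pi_cap) <= spec.zero_level:
        import warnings

        warnings.warn(
            "requested zero level unreachable under the per-taxon cap; "
            "using the capped maximum",
            stacklevel=2,
        )
        t = pi_cap
    else:
        lo, hi = 0.0, pi_cap
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if marginal(mid) < spec.zero_level:
                lo = mid
            else:
                hi = mid
        t = 0.5 * (lo + hi)
    if t > 0:
        pi = np.clip(t * v, 0.0, pi_cap)
        mask = rng.random(size=counts.shape) < pi[None, :]
        counts[mask] = 0
    return counts


def simulate_dataset(
    spec: ScenarioSpec, rng: np.random.Generator | None = None
) -> SyntheticDataset:
    """Generate one full study (genes, taxa, outcome, truth labels)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    genes, outcome = simulate_genes(spec, rng)
    taxa = simulate_taxa(genes, outcome, spec, rng)
    truth = np.zeros(spec.n_taxa, dtype=bool)
    true_gene_sets: dict[int, np.ndarray] = {}
    tb = spec.taxon_blocks
    for blk in TRUE_MEDIATOR_BLOCKS:
        sl = tb[blk]
        truth[sl] = True
        gsl = spec.gene_blocks[TAXON_BLOCK_GENE_PARTNER[blk]]
        for j in range(sl.start, sl.stop):
            true_gene_sets[j] = np.arange(gsl.start, gsl.stop)
    return SyntheticDataset(
        genes=genes,
        taxa=taxa,
        outcome=outcome,
        truth=truth,
        true_gene_sets=true_gene_sets,
        spec=spec,
    )


def build_scenario(setting: str, **overrides) -> list[ScenarioSpec]:
    """The scenario grid of one simulation study.

    ``"i"``   : sample size {40, 80} x zero level {0.50, 0.80}, signal 0.5.
    ``"ii"``  : signal {0.5, 0.1} x zero level {0.50, 0.80}, n = 40/group.
    ``"iii"`` : dispersion c {100, 1000} x signal {0.5, 0.1},
                zero level 0.80, n = 40/group.

    Keyword overrides (e.g. ``n_genes=50, n_taxa=50``) apply to every
    spec in the grid.
    """
    base = ScenarioSpec()
    grids: dict[str, list[ScenarioSpec]] = {
        "i": [
            replace(base, n_per_group=n, zero_level=z, signal_strength=0.5,
                    label=f"i_n{n}_z{int(z * 100)}")
            for n in (40, 80)
            for z in (0.5, 0.8)
        ],
        "ii": [
            replace(base, n_per_group=40, zero_level=z, signal_strength=s,
                    label=f"ii_s{int(s * 100)}_z{int(z * 100)}")
            for s in (0.5, 0.1)
            for z in (0.5, 0.8)
        ],
        "iii": [
            replace(base, n_per_group=40, zero_level=0.8, signal_strength=s,
                    dispersion_c=c, label=f"iii_c{int(c)}_s{int(s * 100)}")
            for c in (100.0, 1000.0)
            for s in (0.5, 0.1)
        ],
    }
    if setting not in grids:
        raise ValueError(f"unknown setting {setting!r}; expected one of {list(grids)}")
    specs = grids[setting]
    if overrides:
        specs = [replace(s, **overrides) for s in specs]
    return specs
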