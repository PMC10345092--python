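"""Synthetic Patch-seq-like datasets with full ground truth.

The generator emulates the statistical structure the analysis assumes: cells
from several donors and t-types, negative-binomial counts with library-size
variation, three gene sets with configurable pairwise overlap, and a latent
per-cell "size" factor z that jointly elevates total dendritic length, AP rise
speed, and a planted module of genes.  Planted genes receive a multiplicative
expression effect exp(beta * z) whose beta is calibrated by an internal pilot
simulation to hit a target Pearson correlation between log10(CPM+1) expression
and the (linear-in-z) AP phenotype.  All remaining genes are null.

Randomness flows from one seed through fixed-purpose substreams (set
construction, latent factors, library sizes, counts, phenotypes), so the gene
universe and set memberships do not depend on how many cells are drawn.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .ephys import Sweep
from .io import ExpressionMatrix, GeneSet

__all__ = [
    "TTypeSpec",
    "SyntheticConfig",
    "PlantedGene",
    "SyntheticTruth",
    "SyntheticDataset",
    "default_t_types",
    "generate_gene_sets",
    "generate_dataset",
    "generate_traces",
]


@dataclass(frozen=True)
class TTypeSpec:
    """One transcriptomic type: cell count, depth range within L2/L3, and the
    additive shift it applies to the latent size factor."""

    name: str
    n_cells: int
    depth_range: tuple[float, float] = (0.0, 1.0)
    z_shift: float = 0.0


def default_t_types(n_cells_per_type: int = 25) -> tuple[TTypeSpec, ...]:
    """Six L2/L3 glutamatergic types with paper-like depth ranges and the
    L3-elevated latent-factor pattern (FREM3-deep and CARM1P1 largest)."""
    return (
        TTypeSpec("LTK", n_cells_per_type, (0.00, 0.25), -0.5),
        TTypeSpec("L2 FREM3", n_cells_per_type, (0.05, 0.30), -0.2),
        TTypeSpec("L3 FREM3", n_cells_per_type, (0.30, 1.00), 0.8),
        TTypeSpec("GLP2R", n_cells_per_type, (0.30, 0.60), 0.0),
        TTypeSpec("CARM1P1", n_cells_per_type, (0.60, 1.00), 1.0),
        TTypeSpec("COL22A1", n_cells_per_type, (0.50, 1.00), -0.3),
    )


@dataclass
class SyntheticConfig:
    """Full parameterization of one synthetic dataset.

    Defaults give a scaled-down Patch-seq-like cohort: 150 cells in six
    t-types from 3 donors, 1000 genes, deep-sequenced libraries (~5e5 reads,
    lognormal spread), three overlapping gene sets with planted
    phenotype-coupled genes at target |r| = 0.5.
    """

    n_donors: int = 3
    t_types: tuple[TTypeSpec, ...] = field(default_factory=default_t_types)
    n_genes: int = 1000
    library_size_mean: float = 5e5
    library_size_sigma: float = 0.35
    baseline_log_sigma: float = 3.0
    nb_dispersion: float = 0.5
    # gene sets: sizes, pairwise overlap fractions (of the first-named set),
    # and the triple overlap fraction (of the first set overall)
    set_sizes: dict[str, int] = field(
        default_factory=lambda: {"IQ": 100, "EA": 160, "HAR": 150}
    )
    pairwise_overlap: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("IQ", "EA"): 0.30, ("IQ", "HAR"): 0.14, ("EA", "HAR"): 0.19}
    )
    triple_overlap: float = 0.05
    # planting
    n_planted: dict[str, int] = field(default_factory=lambda: {"IQ": 8, "EA": 10, "HAR": 10})
    target_r: float = 0.5
    positive_fraction: float = 0.8
    planted_overlap_bias: float = 1.0  # >1 prefers planting genes shared with bias_set
    bias_set: str = "HAR"
    planted_mean_cpm: float = 100.0
    # additive t-type shift on the log expression of (non-planted) set members,
    # in natural-log units per unit of the type's latent shift; this is what
    # makes whole-set scores, not just planted genes, elevated in the large
    # L3-like types
    type_effect_on_set_genes: float = 0.25
    # phenotypes
    tdl_scale: float = 4500.0  # um
    tdl_z_coef: float = 0.35
    tdl_noise: float = 0.15  # multiplicative noise SD
    ap_intercept: float = 300.0  # V/s
    ap_z_coef: float = 60.0  # V/s per latent unit
    ap_noise: float = 30.0  # V/s residual SD
    independent_phenotypes: bool = False  # if True, TDL ignores z (noise only)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_donors <= 0:
            raise ValueError("sizes must be positive")
        if not abs(self.target_r) < 1:
            raise ValueError("target |r| must be < 1")
        for frac in self.pairwise_overlap.values():
            if not 0 <= frac <= 1:
                raise ValueError("overlap fractions must lie in [0, 1]")
        for name in self.set_sizes:
            if self.set_sizes[name] <= 0:
                raise ValueError("set sizes must be positive")

    @property
    def n_cells(self) -> int:
        return sum(t.n_cells for t in self.t_types)


@dataclass(frozen=True)
class PlantedGene:
    gene: str
    set_name: str
    sign: int
    target_r: float
    beta: float


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset."""

    planted: dict[str, PlantedGene]
    set_memberships: dict[str, frozenset[str]]
    z: np.ndarray  # latent size factor per cell
    type_shifts: dict[str, float]
    beta_magnitude: float


@dataclass
class SyntheticDataset:
    matrix: ExpressionMatrix  # counts
    metadata: pd.DataFrame
    phenotypes: pd.DataFrame
    gene_sets: list[GeneSet]
    truth: SyntheticTruth


def _stream(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# gene sets with controlled overlaps
# ---------------------------------------------------------------------------

def _region_counts(config: SyntheticConfig) -> dict[frozenset[str], int]:
    """Counts for every disjoint membership region, from sizes and overlaps."""
    names = list(config.set_sizes)
    sizes = config.set_sizes
    pair_count: dict[frozenset[str], int] = {}
    for (a, b), frac in config.pairwise_overlap.items():
        if a not in sizes or b not in sizes:
            raise ValueError(f"overlap refers to unknown set: {(a, b)}")
        pair_count[frozenset((a, b))] = round(frac * sizes[a])
    for a, b in itertools.combinations(names, 2):
        pair_count.setdefault(frozenset((a, b)), 0)

    regions: dict[frozenset[str], int] = {}
    if len(names) == 3:
        triple = round(config.triple_overlap * sizes[names[0]])
        triple = min(triple, *(pair_count[k] for k in pair_count))
        regions[frozenset(names)] = triple
        for key, cnt in pair_count.items():
            regions[key] = cnt - triple
    elif len(names) == 2:
        key = frozenset(names)
        regions[key] = pair_count[key]
    else:
        triple = 0
    for name in names:
        shared = sum(cnt for key, cnt in regions.items() if name in key)
        only = sizes[name] - shared
        if only < 0:
            raise ValueError(
                f"infeasible overlap spec: set {name!r} size {sizes[name]} < "
                f"sum of its overlap regions ({shared})"
            )
        regions[frozenset((name,))] = only
    union = sum(regions.values())
    if union > config.n_genes:
        raise ValueError(f"union of sets ({union}) exceeds n_genes ({config.n_genes})")
    return regions


def generate_gene_sets(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> list[GeneSet]:
    """Build the gene sets with the configured pairwise (and triple) overlaps.

    Realized pairwise overlap counts equal round(fraction x size of the
    first-named set) exactly (up to the shared triple region for 3 sets).
    """
    rng = rng or _stream(config.seed, 1)
    regions = _region_counts(config)
    all_genes = _gene_ids(config.n_genes)
    union_n = sum(regions.values())
    pool = list(rng.choice(config.n_genes, size=union_n, replace=False))
    members: dict[str, set[str]] = {name: set() for name in config.set_sizes}
    pos = 0
    for key in sorted(regions, key=lambda k: (-len(k), sorted(k))):
        cnt = regions[key]
        chunk = [all_genes[i] for i in pool[pos:pos + cnt]]
        pos += cnt
        for name in key:
            members[name].update(chunk)
    return [
        GeneSet(name, frozenset(members[name]), "synthetic")
        for name in config.set_sizes
    ]


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


# ---------------------------------------------------------------------------
# beta calibration
# ---------------------------------------------------------------------------

def _pilot_rho(
    beta: float,
    mean_cpm: float,
    lib_mean: float,
    lib_sigma: float,
    dispersion: float,
    z_mean: float,
    z_sd: float,
    n_pilot: int,
    pilot_seed: int,
) -> float:
    """Correlation of log10(CPM+1) with z for one gene under effect beta.

    Re-seeded identically per evaluation so the bisection sees a smooth
    function of beta (common random numbers for z and library sizes).
    """
    rng = np.random.default_rng(pilot_seed)
    z = z_mean + z_sd * rng.standard_normal(n_pilot)
    lib = lib_mean * np.exp(rng.normal(-lib_sigma**2 / 2, lib_sigma, n_pilot))
    # normalize so the gene's expected CPM stays near mean_cpm
    scale = math.exp(beta * z_mean + 0.5 * (beta * z_sd) ** 2)
    mu = lib * (mean_cpm / 1e6) * np.exp(beta * z) / scale
    size = 1.0 / dispersion
    counts = rng.negative_binomial(size, size / (size + mu))
    expr = np.log10(counts / lib * 1e6 + 1.0)
    if expr.std() == 0:
        return 0.0
    return float(np.corrcoef(expr, z)[0, 1])


@lru_cache(maxsize=64)
def _calibrate_beta(
    target_rho_ez: float,
    mean_cpm: float,
    lib_mean: float,
    lib_sigma: float,
    dispersion: float,
    z_mean: float,
    z_sd: float,
    beta_hi: float = 8.0,
    n_pilot: int = 20000,
    pilot_seed: int = 20230713,
) -> float:
    """Bisection for the beta giving corr(log10(CPM+1), z) = target.

    Deterministic (fixed internal pilot seed, independent of the dataset
    seed); cached per configuration.  Raises with the attainable bound when
    the target exceeds what expression sampling noise allows.
    """
    args = (mean_cpm, lib_mean, lib_sigma, dispersion, z_mean, z_sd, n_pilot, pilot_seed)
    # rho(beta) rises, peaks, then decays (mean-preserving scaling drives most
    # counts to zero at extreme beta), so scan a grid and bisect the rising branch
    grid = np.linspace(0.0, beta_hi, 33)
    rhos = np.array([_pilot_rho(b, *args) for b in grid])
    peak = int(np.argmax(rhos))
    if target_rho_ez > rhos[peak]:
        raise ValueError(
            f"target expression-latent correlation {target_rho_ez:.3f} is not "
            f"attainable; maximum ~{rhos[peak]:.3f} at beta={grid[peak]:.2f}"
        )
    lo, hi = 0.0, float(grid[peak])
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        if _pilot_rho(mid, *args) < target_rho_ez:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _latent_params(config: SyntheticConfig) -> tuple[float, float]:
    """Mean and SD of the latent factor across the configured type mixture."""
    weights = np.array([t.n_cells for t in config.t_types], dtype=float)
    weights /= weights.sum()
    shifts = np.array([t.z_shift for t in config.t_types])
    mean = float(weights @ shifts)
    var = 1.0 + float(weights @ (shifts - mean) ** 2)
    return mean, math.sqrt(var)


def required_latent_correlation(config: SyntheticConfig) -> float:
    """Expression-latent correlation needed to hit target_r against the AP
    phenotype, given AP = intercept + coef*z + noise."""
    rho_zp = config.ap_z_coef / math.hypot(config.ap_z_coef, config.ap_noise)
    required = abs(config.target_r) / rho_zp
    if required >= 1:
        raise ValueError(
            f"target r {config.target_r} infeasible: phenotype noise caps the "
            f"attainable correlation at {rho_zp:.3f}"
        )
    return required


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one complete dataset (counts, metadata, phenotypes, sets, truth).

    Identical config + seed give bit-identical outputs.
    """
    gene_ids = _gene_ids(config.n_genes)
    gene_sets = generate_gene_sets(config, _stream(config.seed, 1))
    members = {s.name: s.members for s in gene_sets}

    # ---- choose planted genes per set --------------------------------------
    rng_struct = _stream(config.seed, 0)
    z_mean, z_sd = _latent_params(config)
    rho_needed = required_latent_correlation(config)
    beta_mag = _calibrate_beta(
        rho_needed,
        config.planted_mean_cpm,
        config.library_size_mean,
        config.library_size_sigma,
        config.nb_dispersion,
        z_mean,
        z_sd,
    )

    bias_members = members.get(config.bias_set, frozenset())
    planted: dict[str, PlantedGene] = {}
    for set_name, n_pl in config.n_planted.items():
        if n_pl == 0:
            continue
        candidates = sorted(members[set_name] - set(planted))
        if len(candidates) < n_pl:
            raise ValueError(
                f"cannot plant {n_pl} genes in set {set_name!r}: only "
                f"{len(candidates)} unplanted members"
            )
        w = np.array(
            [config.planted_overlap_bias if g in bias_members else 1.0 for g in candidates]
        )
        chosen = rng_struct.choice(candidates, size=n_pl, replace=False, p=w / w.sum())
        for g in chosen:
            sign = 1 if rng_struct.random() < config.positive_fraction else -1
            planted[str(g)] = PlantedGene(str(g), set_name, sign, config.target_r, beta_mag)

    # ---- cells: types, donors, depths, latent factor -----------------------
    cells, types, donors, depths = [], [], [], []
    i = 0
    for t in config.t_types:
        for j in range(t.n_cells):
            cells.append(f"C{i:04d}")
            types.append(t.name)
            donors.append(f"D{j % config.n_donors + 1}")
            i += 1
        lo, hi = t.depth_range
        depths.extend(rng_struct.uniform(lo, hi, t.n_cells))
    n_cells = len(cells)

    rng_z = _stream(config.seed, 2)
    shift_by_type = {t.name: t.z_shift for t in config.t_types}
    z = np.array([shift_by_type[t] for t in types]) + rng_z.standard_normal(n_cells)

    # ---- library sizes and counts ------------------------------------------
    rng_lib = _stream(config.seed, 3)
    lib = config.library_size_mean * np.exp(
        rng_lib.normal(-config.library_size_sigma**2 / 2, config.library_size_sigma, n_cells)
    )

    rng_counts = _stream(config.seed, 4)
    planted_frac = config.planted_mean_cpm / 1e6
    w_null = np.exp(rng_counts.normal(0.0, config.baseline_log_sigma, config.n_genes))
    frac = np.empty(config.n_genes)
    planted_cols = np.array([gene_ids.index(g) for g in planted], dtype=int)
    is_planted = np.zeros(config.n_genes, dtype=bool)
    is_planted[planted_cols] = True
    budget = 1.0 - planted_frac * is_planted.sum()
    if budget <= 0:
        raise ValueError("planted genes exceed the expression budget")
    frac[~is_planted] = w_null[~is_planted] / w_null[~is_planted].sum() * budget
    frac[is_planted] = planted_frac

    mu = lib[:, None] * frac[None, :]
    if config.type_effect_on_set_genes != 0.0:
        set_union: set[str] = set()
        for m in members.values():
            set_union |= m
        set_cols = np.array(
            [i for i, g in enumerate(gene_ids) if g in set_union and g not in planted],
            dtype=int,
        )
        if len(set_cols):
            shift_per_cell = np.array([shift_by_type[t] for t in types])
            mult = np.exp(config.type_effect_on_set_genes * shift_per_cell)
            mult = mult / mult.mean()  # preserve the average expression level
            mu[:, set_cols] = mu[:, set_cols] * mult[:, None]
    if len(planted_cols):
        betas = np.array([planted[gene_ids[c]].sign * beta_mag for c in planted_cols])
        scale = np.exp(betas * z_mean + 0.5 * (betas * z_sd) ** 2)
        mu[:, planted_cols] = mu[:, planted_cols] * np.exp(np.outer(z, betas)) / scale
    size = 1.0 / config.nb_dispersion
    counts = rng_counts.negative_binomial(size, size / (size + mu)).astype(float)
    matrix = ExpressionMatrix(cells, gene_ids, counts, "counts")

    # ---- phenotypes --------------------------------------------------------
    rng_ph = _stream(config.seed, 5)
    tdl_z = np.zeros(n_cells) if config.independent_phenotypes else z
    tdl_noise = np.clip(rng_ph.normal(0.0, config.tdl_noise, n_cells), -0.9, None)
    tdl = config.tdl_scale * np.exp(config.tdl_z_coef * tdl_z) * (1.0 + tdl_noise)
    ap = config.ap_intercept + config.ap_z_coef * z + rng_ph.normal(0, config.ap_noise, n_cells)
    ap = np.clip(ap, 1.0, None)  # physical floor; essentially never binds at defaults

    metadata = pd.DataFrame(
        {
            "cell_id": cells,
            "donor_id": donors,
            "area": "MTG",
            "cell_class": "glutamatergic",
            "t_type": types,
            "relative_depth": depths,
        }
    )
    phenotypes = pd.DataFrame({"cell_id": cells, "tdl": tdl, "ap_rise_speed": ap})
    truth = SyntheticTruth(
        planted=planted,
        set_memberships=members,
        z=z,
        type_shifts=shift_by_type,
        beta_magnitude=beta_mag,
    )
    return SyntheticDataset(matrix, metadata, phenotypes, gene_sets, truth)


# ---------------------------------------------------------------------------
# spike traces
# ---------------------------------------------------------------------------

GAUSS_SUPPORT_SIGMAS = 8.0


def generate_traces(
    spike_times: list,
    amplitudes: float | list = 100.0,
    sampling_rate: float = 50_000.0,
    duration: float = 0.5,
    sigma: float = 3e-4,
    baseline: float = -70.0,
    noise_sd: float = 0.0,
    step_currents: list | None = None,
    seed: int = 0,
) -> tuple[list[Sweep], list[np.ndarray]]:
    """Synthetic current-clamp sweeps with Gaussian-bump spikes.

    ``spike_times`` is one sequence of spike centers per sweep; each spike is
    ``A * exp(-(t - t0)^2 / (2 sigma^2))`` above baseline, whose maximum
    derivative is analytically ``A exp(-1/2) / sigma`` (mV/s; /1000 in V/s).
    Returns the sweeps and, per sweep, the ground-truth max dV/dt (V/s) of
    each spike.  Spikes closer than the waveform support (8 sigma) are an
    error.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    amps = amplitudes if isinstance(amplitudes, (list, tuple, np.ndarray)) else None
    sweeps, truths = [], []
    for si, centers in enumerate(spike_times):
        centers = np.sort(np.asarray(centers, dtype=float))
        if np.any(centers < 0) or np.any(centers > duration):
            raise ValueError("spike times must lie within the sweep duration")
        if len(centers) > 1 and np.min(np.diff(centers)) < GAUSS_SUPPORT_SIGMAS * sigma:
            raise ValueError(
                f"spikes closer than the waveform support ({GAUSS_SUPPORT_SIGMAS} sigma)"
            )
        a = float(amps[si]) if amps is not None else float(amplitudes)
        v = np.full(n, baseline)
        for t0 in centers:
            v = v + a * np.exp(-((t - t0) ** 2) / (2 * sigma**2))
        if noise_sd > 0:
            v = v + rng.normal(0, noise_sd, n)
        current = step_currents[si] if step_currents is not None else float("nan")
        sweeps.append(Sweep(t, v, sampling_rate, current))
        truths.append(np.full(len(centers), a * math.exp(-0.5) / sigma / 1000.0))
    return sweeps, truths
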