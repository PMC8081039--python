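"""Synthetic data generators with known ground truth.

Every input class the pipeline consumes can be generated here: sinuous worm
images with an analytically known centerline length, logistic growth
trajectories with developmental event times, negative-binomial count
matrices with known size factors / dispersion trend / spiked fold changes,
smooth reference time courses, and log-normal lipid abundance tables with
injected non-detects and group effects.

All generators are pure functions of their arguments including ``seed``:
calling twice with identical arguments yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, ndimage, optimize
from skimage.filters import gaussian as _gaussian_blur

from .growthdev import DevEvents, GrowthTrajectory

__all__ = [
    "SynthWormTruth",
    "SynthCountsTruth",
    "SynthLipidTruth",
    "gen_worm_image",
    "gen_growth_series",
    "gen_counts",
    "gen_reference_timecourse",
    "gen_lipid_table",
]


# ---------------------------------------------------------------------------
# Truth records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthWormTruth:
    """Ground truth for a generated worm image.

    ``centerline_length_um`` is the arc length of the generating parametric
    curve obtained by numerical quadrature, not a rasterized estimate.
    """

    centerline_length_um: float
    mask: np.ndarray
    px_size_um: float
    centerline_px: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.centerline_length_um <= 0:
            raise ValueError("centerline_length_um must be positive")


@dataclass(frozen=True)
class SynthCountsTruth:
    """Ground truth for a generated count matrix."""

    size_factors: pd.Series
    gene_means: pd.Series
    dispersions: pd.Series
    de_genes: frozenset
    log2_fold_changes: pd.Series


@dataclass(frozen=True)
class SynthLipidTruth:
    """Ground truth for a generated lipid table."""

    affected_lipids: frozenset
    effect_multipliers: pd.Series
    missing_cells: frozenset


# ---------------------------------------------------------------------------
# Worm images
# ---------------------------------------------------------------------------

def _sine_arclength(u_max: float, amplitude: float, period: float) -> float:
    """Arc length of x=u, y=A sin(2*pi*u/P) for u in [0, u_max] by quadrature."""
    if amplitude == 0:
        return u_max
    w = 2.0 * np.pi / period
    val, _ = integrate.quad(
        lambda u: np.hypot(1.0, amplitude * w * np.cos(w * u)), 0.0, u_max,
        limit=200,
    )
    return val


def gen_worm_image(
    arclength_um: float,
    px_size_um: float = 1.0,
    amplitude_um: float = 20.0,
    period_um: float = 120.0,
    thickness_px: float = 9.0,
    noise_sd: float = 0.03,
    seed: int = 0,
    pad_px: int = 16,
    background_gradient: float = 0.05,
) -> tuple[np.ndarray, SynthWormTruth]:
    """Render one bright sinuous worm on a dark background.

    The centerline is a parametric sine of the given amplitude and period,
    rotated by a seed-dependent angle, rendered by stamping disks of radius
    ``thickness_px / 2`` along it (giving blunt, rounded ends like a real
    larva).  The returned truth carries the exact arc length of the
    generating curve, the noise-free binary mask and the pixel size.

    Parameters
    ----------
    arclength_um
        Requested centerline arc length in micrometres; the generating
        curve's extent is solved so its quadrature arc length matches this
        to better than 0.5%.
    noise_sd
        Standard deviation of additive Gaussian intensity noise on a
        [0, 1] intensity scale.
    background_gradient
        Peak-to-peak amplitude of a smooth left-to-right illumination
        gradient added to the background.
    """
    if arclength_um <= 0:
        raise ValueError("arclength_um must be positive")
    if thickness_px < 1:
        raise ValueError("thickness_px must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if arclength_um < 2.0 * px_size_um:
        raise ValueError("arclength shorter than 2 px cannot be rendered")

    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, np.pi)

    # Solve for the parameter extent giving the requested arc length.
    if amplitude_um == 0:
        u_max = arclength_um
    else:
        u_max = optimize.brentq(
            lambda u: _sine_arclength(u, amplitude_um, period_um) - arclength_um,
            arclength_um / 10.0,
            arclength_um * 1.001,
            xtol=1e-9 * arclength_um,
        )
    true_len = _sine_arclength(u_max, amplitude_um, period_um)

    # Dense centerline samples (~4 per pixel) in micrometres, then rotate.
    n_samples = max(int(np.ceil(4.0 * arclength_um / px_size_um)), 16)
    u = np.linspace(0.0, u_max, n_samples)
    x = u
    y = amplitude_um * np.sin(2.0 * np.pi * u / period_um) if amplitude_um else np.zeros_like(u)
    ct, st = np.cos(theta), np.sin(theta)
    xr = ct * x - st * y
    yr = st * x + ct * y

    # To pixel coordinates with padding.
    col = xr / px_size_um
    row = yr / px_size_um
    margin = pad_px + thickness_px
    col = col - col.min() + margin
    row = row - row.min() + margin
    n_rows = int(np.ceil(row.max() + margin))
    n_cols = int(np.ceil(col.max() + margin))

    # Rasterize the centerline, then dilate to a tube via the Euclidean
    # distance transform (exact disk stamping).
    centerline_grid = np.zeros((n_rows, n_cols), dtype=bool)
    centerline_grid[np.round(row).astype(int), np.round(col).astype(int)] = True
    dist = ndimage.distance_transform_edt(~centerline_grid)
    mask = dist <= thickness_px / 2.0

    image = np.where(mask, 0.85, 0.15).astype(float)
    image = _gaussian_blur(image, sigma=1.0, preserve_range=True)
    if background_gradient:
        image = image + background_gradient * np.linspace(-0.5, 0.5, n_cols)[None, :]
    if noise_sd:
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    truth = SynthWormTruth(
        centerline_length_um=float(true_len),
        mask=mask,
        px_size_um=float(px_size_um),
        centerline_px=np.column_stack([row, col]),
    )
    return image, truth


# ---------------------------------------------------------------------------
# Growth trajectories
# ---------------------------------------------------------------------------

def gen_growth_series(
    l_max_um: float = 1000.0,
    rate_per_h: float = 0.12,
    shift_h: float = 30.0,
    t_end_h: float = 65.0,
    dt_min: float = 3.0,
    noise_sd: float = 0.0,
    t_hatch_h: float = 12.0,
    t_first_egg_h: float = 60.0,
    seed: int = 0,
    animal_id: str = "synthetic",
) -> tuple[GrowthTrajectory, DevEvents]:
    """Simulate one animal's length-vs-time series plus its event times.

    Lengths follow the 3-parameter logistic
    ``L(t) = l_max / (1 + exp(-rate * (t - shift)))`` sampled every
    ``dt_min`` minutes on [0, t_end_h], multiplied by i.i.d. Gaussian
    factors ``1 + N(0, noise_sd)`` (so ``noise_sd=0.05`` means 5%
    multiplicative noise).  Defaults mirror a long-term imaging run: one
    frame every 3 min for about 65 h from egg to egg-laying adult.
    """
    if l_max_um <= 0:
        raise ValueError("l_max_um must be positive")
    if rate_per_h <= 0:
        raise ValueError("rate_per_h must be positive")
    if not (0 <= t_hatch_h < t_first_egg_h <= t_end_h):
        raise ValueError("need 0 <= t_hatch_h < t_first_egg_h <= t_end_h")

    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_end_h + 1e-9, dt_min / 60.0)
    lengths = l_max_um / (1.0 + np.exp(-rate_per_h * (times - shift_h)))
    if noise_sd:
        lengths = lengths * (1.0 + rng.normal(0.0, noise_sd, size=times.shape))
        lengths = np.maximum(lengths, 1e-6)

    traj = GrowthTrajectory(animal_id=animal_id, times_h=times, lengths_um=lengths)
    events = DevEvents(t_laid_h=0.0, t_hatch_h=t_hatch_h, t_first_egg_h=t_first_egg_h)
    return traj, events


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB draws with variance mu + alpha*mu^2; alpha -> 0 degrades to Poisson."""
    out = np.empty(mean.shape, dtype=np.int64)
    poisson = alpha < 1e-12
    if poisson.any():
        out[poisson] = rng.poisson(mean[poisson])
    nb = ~poisson
    if nb.any():
        r = 1.0 / alpha[nb]
        p = r / (r + mean[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


def gen_counts(
    n_genes: int = 5000,
    n_per_group: int = 5,
    size_factors: np.ndarray | None = None,
    mean_law: tuple[float, float] = (4.0, 1.5),
    trend_params: tuple[float, float] = (0.01, 1.0),
    frac_de: float = 0.1,
    lfc: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, SynthCountsTruth]:
    """Simulate a two-group gene x sample NB count matrix with known truth.

    Gene base means are log-normal ``exp(N(mean_law))``; dispersions follow
    the trend ``alpha(mu) = a0 + a1 / mu`` with ``(a0, a1) = trend_params``;
    a fraction ``frac_de`` of genes in the "test" group get a log2 fold
    change of ``+/- lfc`` (sign random per gene).  Counts for sample ``j``
    are NB with mean ``sf_j * mu_i * 2**(lfc_i * group_j)``.

    Returns ``(counts, groups, truth)`` where ``groups`` maps sample id to
    "control"/"test" and non-DE genes have log2 fold change exactly 0.
    """
    if not 0.0 <= frac_de <= 1.0:
        raise ValueError("frac_de must be in [0, 1]")
    rng = np.random.default_rng(seed)

    n_samples = 2 * n_per_group
    if size_factors is None:
        size_factors = np.exp(rng.normal(0.0, 0.25, size=n_samples))
        size_factors /= np.exp(np.mean(np.log(size_factors)))
    size_factors = np.asarray(size_factors, dtype=float)
    if (size_factors <= 0).any():
        raise ValueError("size_factors must be positive")

    genes = [f"g{i:05d}" for i in range(n_genes)]
    samples = [f"control_{j}" for j in range(n_per_group)] + [
        f"test_{j}" for j in range(n_per_group)
    ]
    group_ind = np.array([0] * n_per_group + [1] * n_per_group)

    mu = np.exp(rng.normal(mean_law[0], mean_law[1], size=n_genes))
    a0, a1 = trend_params
    alpha = a0 + a1 / mu

    n_de = int(round(frac_de * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    log2fc = np.zeros(n_genes)
    log2fc[de_idx] = lfc * rng.choice([-1.0, 1.0], size=n_de)

    mean_mat = (
        size_factors[None, :]
        * mu[:, None]
        * 2.0 ** (log2fc[:, None] * group_ind[None, :])
    )
    counts = _nb_draw(rng, mean_mat, np.broadcast_to(alpha[:, None], mean_mat.shape).copy())

    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    groups = pd.Series(
        ["control"] * n_per_group + ["test"] * n_per_group, index=samples, name="group"
    )
    truth = SynthCountsTruth(
        size_factors=pd.Series(size_factors, index=samples),
        gene_means=pd.Series(mu, index=genes),
        dispersions=pd.Series(alpha, index=genes),
        de_genes=frozenset(np.asarray(genes)[de_idx]),
        log2_fold_changes=pd.Series(log2fc, index=genes),
    )
    return counts_df, groups, truth


def gen_reference_timecourse(
    n_timepoints: int = 10,
    n_genes: int = 2000,
    smoothness: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a smooth reference developmental time course.

    Each gene's expected expression moves monotonically (in expectation) on
    the log scale across timepoints with a gene-specific slope; observed
    counts are NB around those means with dispersion ``smoothness`` (small
    values give a smoother course).  Returns ``(counts, timepoint_labels)``
    with one column per timepoint labelled ``1..n_timepoints``.
    """
    if n_timepoints < 3:
        raise ValueError("n_timepoints must be >= 3")
    rng = np.random.default_rng(seed)

    genes = [f"g{i:05d}" for i in range(n_genes)]
    samples = [f"t{k + 1:02d}" for k in range(n_timepoints)]
    t = np.linspace(-1.0, 1.0, n_timepoints)

    base = rng.normal(4.0, 1.0, size=n_genes)
    slope = rng.normal(0.0, 1.2, size=n_genes)
    log_mean = base[:, None] + slope[:, None] * t[None, :]
    mean = np.exp(log_mean)
    alpha = np.full(mean.shape, max(smoothness, 0.0))
    counts = _nb_draw(rng, mean, alpha)

    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    labels = pd.Series(np.arange(1, n_timepoints + 1), index=samples, name="timepoint")
    return counts_df, labels


# ---------------------------------------------------------------------------
# Lipid tables
# ---------------------------------------------------------------------------

def gen_lipid_table(
    n_lipids: int = 60,
    class_labels: tuple[str, ...] = ("LPC", "LPE", "PC", "PE", "TG", "SM"),
    n_samples_per_group: int = 5,
    missing_prob: float = 0.0,
    effect_multipliers: dict[str, float] | None = None,
    noise_sd_log10: float = 0.08,
    sample_scale_sd_log10: float = 0.1,
    seed: int = 0,
) -> tuple["LipidTable", SynthLipidTruth]:
    """Simulate an internal-standard-corrected lipid abundance table.

    Abundances are log-normal per lipid with two noise components: an
    independent per-cell replicate noise (``noise_sd_log10``, default 0.08
    in log10 units, i.e. roughly 20% CV — typical for internal-standard
    corrected LC-MS biological replicates) and a per-sample global scale
    factor (``sample_scale_sd_log10``) emulating extraction/loading
    variation, which total-abundance normalization is designed to remove.
    Lipids named in ``effect_multipliers`` are multiplied by that factor in
    the "test" group.  Non-detects are injected by zeroing cells
    independently with probability ``missing_prob`` (zero encodes "not
    detected", matching the downstream small-offset logic).  Lipid ids look
    like ``LPC_000``; class labels cycle through ``class_labels``.
    """
    from .lipidome import LipidTable  # local import to avoid cycle

    if not 0.0 <= missing_prob < 1.0:
        raise ValueError("missing_prob must be in [0, 1)")
    rng = np.random.default_rng(seed)
    effect_multipliers = dict(effect_multipliers or {})

    classes = [class_labels[i % len(class_labels)] for i in range(n_lipids)]
    lipids = [f"{classes[i]}_{i:03d}" for i in range(n_lipids)]
    for lid, m in effect_multipliers.items():
        if lid not in lipids:
            raise ValueError(f"unknown lipid id in effect_multipliers: {lid}")
        if m <= 0:
            raise ValueError("effect multipliers must be positive")

    n_samples = 2 * n_samples_per_group
    samples = [f"control_{j}" for j in range(n_samples_per_group)] + [
        f"test_{j}" for j in range(n_samples_per_group)
    ]
    groups = pd.Series(
        ["control"] * n_samples_per_group + ["test"] * n_samples_per_group,
        index=samples,
        name="group",
    )
    timepoints = pd.Series(["50h"] * n_samples, index=samples, name="timepoint")

    base = rng.normal(0.0, 1.0, size=n_lipids)  # log10 scale
    noise = rng.normal(0.0, noise_sd_log10, size=(n_lipids, n_samples))
    sample_scale = rng.normal(0.0, sample_scale_sd_log10, size=n_samples)
    mult = pd.Series(1.0, index=lipids, name="multiplier")
    for lid, m in effect_multipliers.items():
        mult[lid] = float(m)
    log_ab = base[:, None] + noise + sample_scale[None, :]
    log_ab[:, n_samples_per_group:] += np.log10(mult.to_numpy())[:, None]
    abundances = 10.0 ** log_ab

    missing_cells: set[tuple[str, str]] = set()
    if missing_prob > 0:
        miss = rng.random((n_lipids, n_samples)) < missing_prob
        abundances[miss] = 0.0
        for i, j in zip(*np.nonzero(miss)):
            missing_cells.add((lipids[i], samples[j]))

    table = LipidTable(
        abundances=pd.DataFrame(abundances, index=lipids, columns=samples),
        classes=pd.Series(classes, index=lipids, name="class"),
        groups=groups,
        timepoints=timepoints,
    )
    truth = SynthLipidTruth(
        affected_lipids=frozenset(k for k, v in effect_multipliers.items() if v != 1.0),
        effect_multipliers=mult,
        missing_cells=frozenset(missing_cells),
    )
    return table, truth
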