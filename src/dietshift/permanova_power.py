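"""PERMANOVA with paired permutations, plus power / sample-size simulation.

The power framework simulates two-group cohorts whose pairwise-dissimilarity
distribution matches a published mean and standard deviation, with the
between-group separation calibrated by bisection so that the mean realized
omega-squared effect size hits a target.  Each simulated subject contributes
one sample per group (a before/after pair), so ``n_subjects = 70`` means a
140-sample PERMANOVA.

Two simulation methods are available:

* ``"distance"`` (default): pairwise dissimilarities drawn i.i.d. from a
  normal distribution, a constant added to between-group pairs.  This mirrors
  reference implementations that simulate distance matrices directly.
* ``"latent"``: points drawn in a low-dimensional Euclidean space with a
  between-centroid offset; distances affinely standardized per dataset to
  the target mean/sd.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import PairedDesign
from .distances import DistanceMatrix


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    omega2: float
    omega2_raw: float
    n_samples: int
    n_groups: int
    scheme: str  # "free" or "paired"

    def __post_init__(self):
        if not 0.0 <= self.R2 <= 1.0:
            raise ValueError("R2 outside [0, 1]")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p outside (0, 1]")


@dataclass
class PowerConfig:
    mean_dissim: float = 0.52
    sd_dissim: float = 0.06
    omega2_target: float = 0.006
    alpha_level: float = 0.05
    n_subjects: int = 70
    n_reps: int = 500
    n_permutations: int = 200
    seed: int = 0
    method: str = "distance"     # or "latent"
    latent_dim: int = 10

    def __post_init__(self):
        if not 0.0 < self.mean_dissim < 1.0:
            raise ValueError("mean_dissim must lie in (0, 1)")
        if self.sd_dissim <= 0:
            raise ValueError("sd_dissim must be > 0")
        if self.omega2_target < 0:
            raise ValueError("omega2_target must be >= 0")
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        if self.method not in ("distance", "latent"):
            raise ValueError("method must be 'distance' or 'latent'")


@dataclass
class PowerEstimate:
    power: float
    monte_carlo_se: float
    config: PowerConfig
    effect_parameter: float  # calibrated between-group shift / offset


# ---------------------------------------------------------------------------
# PERMANOVA

def _group_masks(groups: np.ndarray) -> list[np.ndarray]:
    return [groups == g for g in np.unique(groups)]


def _ss_decomposition(d2: np.ndarray, masks) -> tuple[float, float, float]:
    n = d2.shape[0]
    sst = d2.sum() / (2.0 * n)
    ssw = 0.0
    for m in masks:
        ng = int(m.sum())
        ssw += d2[np.ix_(m, m)].sum() / (2.0 * ng)
    return sst, ssw, sst - ssw


def _pseudo_f(sst, ssw, ssb, n, k):
    return (ssb / (k - 1)) / (ssw / (n - k))


def _omega2(sst, ssw, ssb, n, k) -> float:
    msw = ssw / (n - k)
    return (ssb - (k - 1) * msw) / (sst + msw)


def _permuted_ssw(d2: np.ndarray, label_matrix: np.ndarray,
                  group_values: np.ndarray) -> np.ndarray:
    """Within-group SS for many label permutations at once.

    label_matrix: (n_perm, n) integer labels.  Uses the identity
    sum_{i<j in g} d2_ij = 1/2 * m_g' D2 m_g with m_g the group indicator.
    """
    ssw = np.zeros(label_matrix.shape[0])
    for g in group_values:
        m = (label_matrix == g).astype(float)
        ng = m[0].sum()  # group sizes are permutation-invariant
        ssw += ((m @ d2) * m).sum(axis=1) / (2.0 * ng)
    return ssw


def _paired_label_matrix(groups, ids, pairing: PairedDesign, n_perm, rng):
    idx = {s: i for i, s in enumerate(ids)}
    before_pos, after_pos = [], []
    covered = set()
    for rec in pairing.records:
        if rec.sample_before not in idx or rec.sample_after not in idx:
            raise ValueError(
                f"subject {rec.subject_id}: sample missing from matrix"
            )
        b, a = idx[rec.sample_before], idx[rec.sample_after]
        if groups[b] == groups[a]:
            raise ValueError(
                f"subject {rec.subject_id}: both samples in one group; the "
                "paired scheme needs before/after in different groups"
            )
        before_pos.append(b)
        after_pos.append(a)
        covered |= {b, a}
    if len(covered) != len(ids):
        raise ValueError("pairing does not cover every sample")
    before_pos = np.asarray(before_pos)
    after_pos = np.asarray(after_pos)
    labels = np.tile(groups, (n_perm, 1))
    flips = rng.random((n_perm, len(before_pos))) < 0.5
    rows = np.repeat(np.arange(n_perm), len(before_pos)).reshape(n_perm, -1)
    b_lab = labels[rows, np.broadcast_to(before_pos, rows.shape)]
    a_lab = labels[rows, np.broadcast_to(after_pos, rows.shape)]
    new_b = np.where(flips, a_lab, b_lab)
    new_a = np.where(flips, b_lab, a_lab)
    labels[rows, np.broadcast_to(before_pos, rows.shape)] = new_b
    labels[rows, np.broadcast_to(after_pos, rows.shape)] = new_a
    return labels


def permanova(
    dist: DistanceMatrix,
    groups,
    n_permutations: int = 2000,
    pairing: PairedDesign | None = None,
    seed: int = 0,
) -> PermanovaResult:
    """Distance-based PERMANOVA with free or subject-paired permutations.

    With `pairing`, permutations swap the before/after group labels
    independently within each subject (restricted 2^subjects scheme).
    The p-value uses the add-one convention: (1 + #{F_perm >= F_obs}) /
    (n_permutations + 1).
    """
    groups = np.asarray(
        [str(g) for g in groups], dtype=object
    )
    if len(groups) != dist.n:
        raise ValueError("groups length mismatch")
    group_values = np.unique(groups)
    k = len(group_values)
    if k < 2:
        raise ValueError("need at least 2 groups")
    sizes = [(groups == g).sum() for g in group_values]
    if min(sizes) < 2:
        raise ValueError("every group needs at least 2 samples")
    n = dist.n
    d2 = dist.data ** 2
    masks = _group_masks(groups)
    sst, ssw, ssb = _ss_decomposition(d2, masks)
    f_obs = _pseudo_f(sst, ssw, ssb, n, k)
    w2_raw = _omega2(sst, ssw, ssb, n, k)

    rng = np.random.default_rng(seed)
    if pairing is not None:
        label_matrix = _paired_label_matrix(
            groups, dist.ids, pairing, n_permutations, rng
        )
    else:
        label_matrix = np.array(
            [rng.permutation(groups) for _ in range(n_permutations)],
            dtype=object,
        )
    ssw_perm = _permuted_ssw(d2, label_matrix, group_values)
    ssb_perm = sst - ssw_perm
    f_perm = (ssb_perm / (k - 1)) / (ssw_perm / (n - k))
    p = (1.0 + (f_perm >= f_obs - 1e-12).sum()) / (n_permutations + 1.0)
    return PermanovaResult(
        pseudo_F=float(f_obs),
        R2=float(ssb / sst),
        p_value=float(p),
        n_permutations=n_permutations,
        omega2=float(max(w2_raw, 0.0)),
        omega2_raw=float(w2_raw),
        n_samples=n,
        n_groups=k,
        scheme="paired" if pairing is not None else "free",
    )


# ---------------------------------------------------------------------------
# power simulation

def _simulate_d2(config: PowerConfig, m: int, effect: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Squared-distance matrix for two groups of m samples each."""
    n = 2 * m
    if config.method == "distance":
        d = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        d[iu] = rng.normal(config.mean_dissim, config.sd_dissim, len(iu[0]))
        d[:m, m:] += effect
        d = np.triu(d, 1)
        d = d + d.T
    else:
        z = rng.standard_normal((n, config.latent_dim))
        z[:m, 0] += effect
        diff = z[:, None, :] - z[None, :, :]
        d = np.sqrt((diff ** 2).sum(axis=2))
        iu = np.triu_indices(n, k=1)
        vals = d[iu]
        vals = (config.mean_dissim
                + config.sd_dissim * (vals - vals.mean()) / vals.std())
        d = np.zeros((n, n))
        d[iu] = vals
        d = d + d.T
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 1e-12) ** 2


def _two_group_stats(d2: np.ndarray, m: int):
    n = 2 * m
    sst = d2.sum() / (2.0 * n)
    ssw = d2[:m, :m].sum() / (2.0 * m) + d2[m:, m:].sum() / (2.0 * m)
    return sst, ssw, sst - ssw


def _mean_omega2(config: PowerConfig, effect: float, n_ref: int,
                 reps: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    m = n_ref
    vals = []
    for _ in range(reps):
        d2 = _simulate_d2(config, m, effect, rng)
        sst, ssw, ssb = _two_group_stats(d2, m)
        vals.append(_omega2(sst, ssw, ssb, 2 * m, 2))
    return float(np.mean(vals))


def calibrate_effect(
    config: PowerConfig,
    n_ref: int = 100,
    reps: int = 300,
    max_effect: float | None = None,
    n_iter: int = 30,
) -> float:
    """Between-group shift whose bias-corrected omega^2 hits the target.

    For the i.i.d.-distance method the expectation ratio has a closed form:
    with w = E[d^2] within (mu^2 + sd^2) and b = E[d^2] between
    ((mu + c)^2 + sd^2), omega^2 = (b - w) / (b + w) independently of n, so
    c solves a quadratic.  The latent method is calibrated by bisection on
    the mean realized omega^2, using one fixed random stream derived from
    the config seed (common random numbers) so the objective is monotone.
    """
    if config.omega2_target == 0.0:
        return 0.0
    if config.method == "distance":
        mu, sd, w2 = config.mean_dissim, config.sd_dissim, config.omega2_target
        if w2 >= 1.0:
            raise ValueError("omega2_target must be < 1")
        a = 2.0 * (mu * mu + sd * sd)
        return float(-mu + np.sqrt(mu * mu + w2 * a / (1.0 - w2)))
    if max_effect is None:
        max_effect = 6.0
    cal_seed = config.seed * 1_000_003 + 17
    hi_val = _mean_omega2(config, max_effect, n_ref, reps, cal_seed)
    lo_val = _mean_omega2(config, 0.0, n_ref, reps, cal_seed)
    if config.omega2_target > hi_val:
        raise ValueError(
            f"omega2_target {config.omega2_target} unreachable; attainable "
            f"range under these dissimilarity parameters is "
            f"[{lo_val:.4g}, {hi_val:.4g}]"
        )
    lo, hi = 0.0, max_effect
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if _mean_omega2(config, mid, n_ref, reps, cal_seed) < config.omega2_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _power_at(config: PowerConfig, n_subjects: int, effect: float,
              seed: int) -> float:
    rng = np.random.default_rng(seed)
    m = n_subjects
    n = 2 * m
    perms = config.n_permutations
    rejections = 0
    for _ in range(config.n_reps):
        d2 = _simulate_d2(config, m, effect, rng)
        sst, ssw, ssb = _two_group_stats(d2, m)
        f_obs = ssb / (ssw / (n - 2))
        pick = np.argsort(rng.random((perms, n)), axis=1)[:, :m]
        mask = np.zeros((perms, n), dtype=bool)
        np.put_along_axis(mask, pick, True, axis=1)
        mf = mask.astype(float)
        mc = (~mask).astype(float)
        ssw_p = (((mf @ d2) * mf).sum(axis=1)
                 + ((mc @ d2) * mc).sum(axis=1)) / (2.0 * m)
        f_perm = (sst - ssw_p) / (ssw_p / (n - 2))
        p = (1.0 + (f_perm >= f_obs - 1e-12).sum()) / (perms + 1.0)
        rejections += p <= config.alpha_level
    return rejections / config.n_reps


def simulate_power(config: PowerConfig,
                   effect: float | None = None) -> PowerEstimate:
    """Monte-Carlo PERMANOVA power for a paired cohort of `n_subjects`.

    Each rep simulates 2*n_subjects samples (one per subject per group),
    runs a two-group PERMANOVA with free label permutations, and counts
    rejections at `alpha_level`.
    """
    if effect is None:
        effect = calibrate_effect(config)
    power = _power_at(config, config.n_subjects, effect,
                      seed=config.seed * 7_919 + 1)
    se = float(np.sqrt(power * (1.0 - power) / config.n_reps))
    return PowerEstimate(power=float(power), monte_carlo_se=se,
                         config=config, effect_parameter=float(effect))


def _isotonic(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: least-squares nondecreasing fit."""
    y = np.asarray(y, dtype=float)
    levels = [[v, 1.0] for v in y]
    merged: list[list[float]] = []
    for lv in levels:
        merged.append(lv)
        while len(merged) > 1 and merged[-2][0] > merged[-1][0]:
            b = merged.pop()
            a = merged.pop()
            w = a[1] + b[1]
            merged.append([(a[0] * a[1] + b[0] * b[1]) / w, w])
    out = []
    for v, w in merged:
        out.extend([v] * int(round(w)))
    return np.asarray(out)


def required_sample_size(
    config: PowerConfig,
    target_power: float = 0.8,
    n_grid=range(30, 111, 10),
) -> dict:
    """Smallest grid n_subjects whose (isotonically smoothed) power >= target.

    The effect parameter is calibrated once and shared across the grid; each
    grid point gets its own seed-derived random stream.  Raises if no grid
    point reaches the target, reporting the maximum attained power.
    """
    grid = sorted(n_grid)
    if not grid:
        raise ValueError("empty grid")
    effect = calibrate_effect(config)
    raw = []
    for i, n in enumerate(grid):
        raw.append(_power_at(config, n, effect,
                             seed=config.seed * 7_919 + 1 + i))
    smoothed = _isotonic(np.asarray(raw))
    ok = np.flatnonzero(smoothed >= target_power)
    result = {
        "grid": list(grid),
        "power_raw": [float(v) for v in raw],
        "power_smoothed": [float(v) for v in smoothed],
        "effect_parameter": float(effect),
        "target_power": target_power,
    }
    if len(ok) == 0:
        raise RuntimeError(
            f"no grid point reaches power {target_power}; max attained "
            f"{smoothed.max():.3f} at n={grid[int(np.argmax(smoothed))]}"
        )
    result["n_required"] = int(grid[int(ok[0])])
    return result
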