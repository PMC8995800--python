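"""Distance-based weight windows.

A *weight window* is a fixed ``n_in x n_out`` matrix ``F`` with entries in
[0, 1] that is multiplied element-wise onto a layer's weight matrix to
suppress selected connections.  Windows here are built from a one-dimensional
node arrangement: input node ``i`` and output node ``j`` are assigned the
Euclidean distance from matrix position ``(i, j)`` to the matrix diagonal —
the line ``j = r*i`` with ``r = n_out/n_in``:

    d_ij = |r*i - j| / sqrt(r**2 + 1)
         = |n_out*i - n_in*j| / sqrt(n_in**2 + n_out**2)

The second form shows the distances are integer multiples of a fixed unit,
which this module exploits for *exact* threshold solving: the set of retained
counts achievable by a diagonal (band) window is enumerable, and requested
reduction ratios snap to the nearest achievable count.

Families
--------
``full``      all-ones (a conventional layer)
``diagonal``  binary band: retain ``d_ij <= threshold`` (inclusive)
``gaussian``  graded band: ``f_ij = exp(-d_ij**2 / (2*sigma**2))``
``stripe``    union of parallel wrapped diagonal bands
``centered``  binary disc around the matrix centre (axes scaled to [0, 1])
``random``    exact-count uniform random retention (seeded)

Conventions: indices are 0-based and the diagonal passes through (0, 0);
retention is inclusive (``d <= t``) so tied cells enter together; the
user-facing *parameter reduction* is the eliminated share
``1 - retained_fraction`` (the retained fraction ``sum(F)/N`` is what is
stored).  The stripe and centered constructions are this package's concrete
reading of schematic descriptions.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DomainError,
    FormatError,
    InvalidWindowError,
    ResourceError,
    SolverError,
)

__all__ = [
    "NodeGeometry",
    "DistanceField",
    "WindowMatrix",
    "node_distance",
    "distance_field",
    "diagonal_window",
    "gaussian_window",
    "stripe_window",
    "centered_window",
    "random_window",
    "full_window",
    "retained_fraction",
    "reduction_ratio",
    "achievable_retained_counts",
    "solve_diagonal_threshold",
    "solve_gaussian_sigma",
    "solve_window",
    "window_to_csv",
    "window_from_csv",
]

BINARY_FAMILIES = frozenset({"full", "diagonal", "stripe", "centered", "random"})
FAMILIES = BINARY_FAMILIES | {"gaussian"}


@dataclass(frozen=True)
class NodeGeometry:
    """Node counts of the two layers a window connects.

    Parameters
    ----------
    n_in : int
        Number of input (preceding-layer) nodes — rows of the weight matrix.
    n_out : int
        Number of output (target-layer) nodes — columns.
    """

    n_in: int
    n_out: int

    def __post_init__(self):
        if not (isinstance(self.n_in, (int, np.integer)) and self.n_in >= 1):
            raise DomainError(f"n_in must be a positive integer, got {self.n_in!r}")
        if not (isinstance(self.n_out, (int, np.integer)) and self.n_out >= 1):
            raise DomainError(f"n_out must be a positive integer, got {self.n_out!r}")

    @property
    def r(self) -> float:
        """Node-count ratio ``n_out / n_in``."""
        return self.n_out / self.n_in

    @property
    def size(self) -> int:
        return self.n_in * self.n_out

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_in, self.n_out)


@dataclass(frozen=True)
class DistanceField:
    """Per-cell distances to the matrix diagonal for one geometry."""

    values: np.ndarray
    geometry: NodeGeometry

    def __post_init__(self):
        if self.values.shape != self.geometry.shape:
            raise DomainError("distance field shape does not match geometry")


@dataclass(frozen=True)
class WindowMatrix:
    """A weight window: values in [0, 1] plus construction metadata.

    ``retained_fraction`` is ``sum(values) / (n_in*n_out)``; the user-facing
    parameter reduction is ``1 - retained_fraction``.
    """

    values: np.ndarray
    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise DomainError(f"window values must be 2-D, got ndim={v.ndim}")
        if self.family not in FAMILIES:
            raise DomainError(f"unknown window family {self.family!r}")
        if np.any(v < 0) or np.any(v > 1):
            raise DomainError("window elements must lie in [0, 1]")
        if v.sum() <= 0:
            raise InvalidWindowError(
                "window retains no weights (all elements are zero)"
            )

    @property
    def retained_fraction(self) -> float:
        return float(self.values.sum() / self.values.size)

    @property
    def reduction(self) -> float:
        """Eliminated share of weights, ``1 - retained_fraction``."""
        return 1.0 - self.retained_fraction

    @property
    def geometry(self) -> NodeGeometry:
        return NodeGeometry(*self.values.shape)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


# ---------------------------------------------------------------------------
# distances


def _check_index(name: str, value: int, bound: int) -> None:
    if not (0 <= value < bound):
        raise DomainError(f"{name}={value} out of range [0, {bound})")


def node_distance(i: int, j: int, geom: NodeGeometry) -> float:
    """Euclidean distance from matrix cell ``(i, j)`` to the diagonal ``j = r*i``."""
    _check_index("i", i, geom.n_in)
    _check_index("j", j, geom.n_out)
    return abs(geom.n_out * i - geom.n_in * j) / math.hypot(geom.n_in, geom.n_out)


def _numerators(geom: NodeGeometry) -> np.ndarray:
    """Integer distance numerators ``|n_out*i - n_in*j|`` for every cell."""
    i = np.arange(geom.n_in, dtype=np.int64)[:, None]
    j = np.arange(geom.n_out, dtype=np.int64)[None, :]
    return np.abs(geom.n_out * i - geom.n_in * j)


def distance_field(geom: NodeGeometry) -> DistanceField:
    """All cell-to-diagonal distances for ``geom`` as a DistanceField."""
    unit = 1.0 / math.hypot(geom.n_in, geom.n_out)
    return DistanceField(values=_numerators(geom) * unit, geometry=geom)


# ---------------------------------------------------------------------------
# window constructors


def full_window(geom: NodeGeometry) -> WindowMatrix:
    """All-ones window: the conventional fully connected layer."""
    return WindowMatrix(np.ones(geom.shape), family="full", params={})


def diagonal_window(geom: NodeGeometry, threshold: float) -> WindowMatrix:
    """Binary band window retaining cells with ``d_ij <= threshold`` (inclusive)."""
    if threshold < 0:
        raise DomainError(f"threshold must be >= 0, got {threshold}")
    d = distance_field(geom).values
    mask = (d <= threshold).astype(float)
    if mask.sum() == 0:
        raise InvalidWindowError(
            f"diagonal window with threshold={threshold} retains no weights"
        )
    return WindowMatrix(mask, family="diagonal", params={"threshold": float(threshold)})


def gaussian_window(geom: NodeGeometry, sigma: float) -> WindowMatrix:
    """Graded window ``f_ij = exp(-d_ij**2 / (2*sigma**2))``."""
    if not sigma > 0:
        raise DomainError(f"sigma must be > 0, got {sigma}")
    d = distance_field(geom).values
    return WindowMatrix(
        np.exp(-(d**2) / (2.0 * sigma**2)),
        family="gaussian",
        params={"sigma": float(sigma)},
    )


def _stripe_distances(geom: NodeGeometry, n_bands: int) -> np.ndarray:
    """Min distance from each cell to any of ``n_bands`` wrapped diagonal lines.

    Band ``b`` is the line ``j = r*i + b*n_out/n_bands``; bands other than the
    main diagonal also contribute their wrap-around copy shifted by ``-n_out``.
    With ``n_bands=1`` this reduces exactly to the plain diagonal distance.
    """
    r = geom.r
    scale = 1.0 / math.sqrt(r * r + 1.0)
    i = np.arange(geom.n_in)[:, None]
    j = np.arange(geom.n_out)[None, :]
    offsets = [b * geom.n_out / n_bands for b in range(n_bands)]
    offsets += [b * geom.n_out / n_bands - geom.n_out for b in range(1, n_bands)]
    d = np.full(geom.shape, np.inf)
    for s in offsets:
        d = np.minimum(d, np.abs(r * i + s - j) * scale)
    return d


def stripe_window(geom: NodeGeometry, n_bands: int, threshold: float) -> WindowMatrix:
    """Union of ``n_bands`` parallel diagonal bands of half-width ``threshold``.

    Band centres are offset by ``n_out/n_bands`` along the output axis and
    wrap around; ``n_bands=1`` degenerates to :func:`diagonal_window`.
    """
    if n_bands < 1:
        raise DomainError(f"n_bands must be >= 1, got {n_bands}")
    if threshold < 0:
        raise DomainError(f"threshold must be >= 0, got {threshold}")
    d = _stripe_distances(geom, n_bands)
    mask = (d <= threshold).astype(float)
    if mask.sum() == 0:
        raise InvalidWindowError("stripe window retains no weights")
    return WindowMatrix(
        mask,
        family="stripe",
        params={"n_bands": int(n_bands), "threshold": float(threshold)},
    )


def _center_distances(geom: NodeGeometry) -> np.ndarray:
    """Distance of each cell from the matrix centre, axes scaled to [0, 1]."""
    u = np.linspace(0.0, 1.0, geom.n_in) if geom.n_in > 1 else np.array([0.5])
    v = np.linspace(0.0, 1.0, geom.n_out) if geom.n_out > 1 else np.array([0.5])
    return np.hypot(u[:, None] - 0.5, v[None, :] - 0.5)


def centered_window(geom: NodeGeometry, radius: float) -> WindowMatrix:
    """Binary disc of given ``radius`` around the matrix centre.

    Row and column indices are each scaled to a common [0, 1] range, so the
    all-ones window is reached at ``radius >= sqrt(2)/2``.
    """
    if radius < 0:
        raise DomainError(f"radius must be >= 0, got {radius}")
    mask = (_center_distances(geom) <= radius).astype(float)
    if mask.sum() == 0:
        raise InvalidWindowError("centered window retains no weights")
    return WindowMatrix(mask, family="centered", params={"radius": float(radius)})


def random_window(geom: NodeGeometry, retain_fraction: float, seed: int) -> WindowMatrix:
    """Exact-count random retention: ``round(retain_fraction * N)`` ones.

    Positions come from a seeded uniform shuffle, so the retained count is
    exact (not Bernoulli-approximate) and the mask is reproducible.
    """
    if not (0.0 < retain_fraction <= 1.0):
        raise DomainError(f"retain_fraction must be in (0, 1], got {retain_fraction}")
    n = geom.size
    k = int(round(retain_fraction * n))
    if k == 0:
        raise InvalidWindowError(
            f"retain_fraction={retain_fraction} rounds to zero retained weights"
        )
    rng = np.random.default_rng(seed)
    flat = np.zeros(n)
    flat[rng.permutation(n)[:k]] = 1.0
    return WindowMatrix(
        flat.reshape(geom.shape),
        family="random",
        params={"retain_fraction": float(retain_fraction), "seed": int(seed)},
    )


# ---------------------------------------------------------------------------
# analysis & solvers


def retained_fraction(window: WindowMatrix) -> float:
    """Retained share ``sum(F) / N``, recomputed from the values."""
    return float(np.asarray(window.values).sum() / np.asarray(window.values).size)


def reduction_ratio(window: WindowMatrix) -> float:
    """Eliminated share ``1 - retained_fraction`` (the user-facing axis)."""
    return 1.0 - retained_fraction(window)


DEFAULT_SIZE_CAP = 10**6


def _threshold_counts(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distinct score levels and cumulative counts ``#(score <= level)``."""
    levels, counts = np.unique(scores, return_counts=True)
    return levels, np.cumsum(counts)


def achievable_retained_counts(
    geom: NodeGeometry, size_cap: int = DEFAULT_SIZE_CAP
) -> list[int]:
    """All retained counts a diagonal window can realize, in increasing order.

    Enumerates ``{#(d_ij <= t)}`` over every distinct distance value plus the
    empty window (count 0).  Exact: distances are compared via their integer
    numerators ``|n_out*i - n_in*j|``.
    """
    if geom.size > size_cap:
        raise ResourceError(
            f"geometry has {geom.size} cells > cap {size_cap}; "
            "use solve_gaussian_sigma for a continuous window instead"
        )
    _, cum = _threshold_counts(_numerators(geom))
    return [0] + [int(c) for c in cum]


def solve_diagonal_threshold(
    geom: NodeGeometry, target_retained: float
) -> tuple[float, float]:
    """Threshold whose retained count is nearest ``target_retained * N``.

    Ties between two achievable counts break toward the larger count.
    Returns ``(threshold, achieved_retained_fraction)``; the achieved value is
    always a member of ``achievable_retained_counts(geom) / N``.
    """
    if not (0.0 < target_retained <= 1.0):
        raise DomainError(f"target_retained must be in (0, 1], got {target_retained}")
    nums = _numerators(geom)
    levels, cum = _threshold_counts(nums)
    n = geom.size
    target = target_retained * n
    counts = np.concatenate(([0], cum))
    gaps = np.abs(counts - target)
    best = np.flatnonzero(gaps == gaps.min())[-1]  # ties -> larger count
    if counts[best] == 0:
        raise InvalidWindowError(
            f"nearest achievable retained count to {target_retained} is 0"
        )
    unit = 1.0 / math.hypot(geom.n_in, geom.n_out)
    threshold = float(levels[best - 1] * unit)
    return threshold, float(counts[best] / n)


def solve_gaussian_sigma(
    geom: NodeGeometry,
    target_retained: float,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> float:
    """Bisection for the sigma whose Gaussian window retains ``target_retained``.

    The map sigma -> sum(F)/N is strictly increasing, so bisection converges;
    the result satisfies ``|retained - target| <= tol``.
    """
    if not (0.0 < target_retained < 1.0):
        raise DomainError(f"target_retained must be in (0, 1), got {target_retained}")
    d2 = distance_field(geom).values ** 2
    n = geom.size

    def retained(sigma: float) -> float:
        return float(np.exp(-d2 / (2.0 * sigma**2)).sum() / n)

    floor = float(np.count_nonzero(d2 == 0)) / n
    if target_retained <= floor:
        raise SolverError(
            f"target {target_retained} not bracketable: the sigma->0 limit "
            f"already retains {floor} (cells on the diagonal line)"
        )
    lo, hi = 1e-9, 1.0
    for _ in range(max_iter):
        if retained(hi) >= target_retained:
            break
        hi *= 2.0
    else:
        raise SolverError(f"could not bracket target {target_retained}: hi={hi}")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = retained(mid)
        if abs(r - target_retained) <= tol:
            return mid
        if r < target_retained:
            lo = mid
        else:
            hi = mid
    raise SolverError(
        f"bisection did not converge to {target_retained} within {max_iter} "
        f"iterations (bracket [{lo}, {hi}])"
    )


def solve_window(
    geom: NodeGeometry,
    family: str,
    reduction: float,
    seed: int | None = None,
    n_bands: int = 2,
) -> WindowMatrix:
    """Build a window of ``family`` at a requested parameter reduction.

    ``reduction`` is the eliminated share in [0, 1).  Binary families snap to
    the nearest achievable retained count (ties toward more retention); the
    Gaussian sigma is solved by bisection.  ``seed`` is required for the
    random family.
    """
    if not (0.0 <= reduction < 1.0):
        raise DomainError(f"reduction must be in [0, 1), got {reduction}")
    target = 1.0 - reduction
    if reduction == 0.0:
        return full_window(geom)
    if family == "full":
        raise DomainError(
            f"a full window cannot realize a nonzero reduction ({reduction})"
        )
    if family == "diagonal":
        threshold, _ = solve_diagonal_threshold(geom, target)
        return diagonal_window(geom, threshold)
    if family == "gaussian":
        return gaussian_window(geom, solve_gaussian_sigma(geom, target))
    if family == "random":
        if seed is None:
            raise DomainError("random windows require a seed")
        return random_window(geom, target, seed)
    if family == "stripe":
        return _snap_binary(
            geom,
            _stripe_distances(geom, n_bands),
            target,
            lambda t: stripe_window(geom, n_bands, t),
        )
    if family == "centered":
        return _snap_binary(
            geom, _center_distances(geom), target, lambda t: centered_window(geom, t)
        )
    raise DomainError(f"unknown window family {family!r}")


def _snap_binary(geom, scores, target_retained, build) -> WindowMatrix:
    """Snap a score-thresholded binary family to the nearest achievable count."""
    levels, cum = _threshold_counts(scores)
    counts = np.concatenate(([0], cum))
    gaps = np.abs(counts - target_retained * geom.size)
    best = np.flatnonzero(gaps == gaps.min())[-1]
    if counts[best] == 0:
        raise InvalidWindowError("requested reduction leaves no retained weights")
    return build(float(levels[best - 1]))


# ---------------------------------------------------------------------------
# export / import


def window_to_csv(window: WindowMatrix, path) -> None:
    """Write a window as dense row-major CSV with a metadata header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# szlab window v1\n")
        fh.write(f"# family: {window.family}\n")
        fh.write(f"# params: {json.dumps(window.params, sort_keys=True)}\n")
        fh.write(f"# retained_fraction: {window.retained_fraction!r}\n")
        np.savetxt(fh, window.values, delimiter=",", fmt="%.17g")


def window_from_csv(path) -> WindowMatrix:
    """Read a window written by :func:`window_to_csv`."""
    header: dict[str, str] = {}
    body = io.StringIO()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                text = line[1:].strip()
                if ":" in text:
                    key, _, val = text.partition(":")
                    header[key.strip()] = val.strip()
            else:
                body.write(line)
    body.seek(0)
    values = np.atleast_2d(np.loadtxt(body, delimiter=","))
    family = header.get("family", "full")
    params = json.loads(header.get("params", "{}"))
    window = WindowMatrix(values, family=family, params=params)
    stored = header.get("retained_fraction")
    if stored is not None and abs(window.retained_fraction - float(stored)) > 1e-9:
        raise FormatError(
            f"stored retained_fraction {stored} disagrees with values "
            f"({window.retained_fraction})"
        )
    return window


def window_heatmap(window: WindowMatrix, path) -> None:
    """Save a grayscale heatmap of the window (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(1.0 - window.values.T, cmap="gray", vmin=0, vmax=1, origin="upper")
    ax.set_xlabel("input node i")
    ax.set_ylabel("output node j")
    ax.set_title(f"{window.family} window, reduction {window.reduction:.1%}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
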