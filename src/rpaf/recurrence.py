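"""Phase-space embedding, recurrence plots, and recurrence quantification.

A scalar series x(1..N) is delay-embedded into m-dimensional vectors
u(i) = (x(i), x(i+tau), ..., x(i+(m-1)tau)), i = 1..M with M = N-(m-1)tau.
The recurrence matrix marks pairs of trajectory points closer than a
threshold eps, chosen as a fraction of the maximum pairwise distance so the
plot is invariant under affine rescaling of the signal. RQA statistics
summarise the plot's diagonal (deterministic) and vertical (laminar)
line structure.

Conventions
-----------
* Recurrence uses the strict inequality ``distance < eps`` (a Heaviside
  step that is 0 at 0), so the pair realising the maximum distance is never
  recurrent even at fraction 1.0.
* The line of identity (main diagonal) is included in the diagonal-line
  statistics by default; ``theiler=1`` excludes it, the usual RQA practice.
* Entropy is the Shannon entropy (natural log) of the normalised
  distribution of diagonal line lengths >= lmin, reported positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from rpaf.ecg import DegenerateSignalError, ParameterError

__all__ = [
    "EmbeddingConfig",
    "PhaseTrajectory",
    "RecurrenceMatrix",
    "LineHistograms",
    "RQAFeatures",
    "embed",
    "recurrence_matrix",
    "line_histograms",
    "rqa_features",
    "rp_to_image",
]


@dataclass
class EmbeddingConfig:
    """Delay-embedding and thresholding parameters.

    ``eps_fraction`` scales the maximum pairwise phase-space distance to get
    the absolute recurrence threshold.
    """

    m: int = 3
    tau: int = 3
    eps_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.m < 1 or self.tau < 1:
            raise ParameterError("m and tau must be >= 1")
        if not 0 < self.eps_fraction <= 1:
            raise ParameterError("eps_fraction must be in (0, 1]")


@dataclass
class PhaseTrajectory:
    """M x m matrix of delay vectors; row i is u(i+1) in 1-based notation."""

    points: np.ndarray
    config: EmbeddingConfig

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class RecurrenceMatrix:
    """Binary M x M recurrence matrix plus the absolute threshold used."""

    matrix: np.ndarray  # bool, symmetric, unit diagonal
    eps: float
    config: EmbeddingConfig

    @property
    def size(self) -> int:
        return self.matrix.shape[0]

    @property
    def recurrence_count(self) -> int:
        return int(self.matrix.sum())


@dataclass
class LineHistograms:
    """Length histograms of maximal diagonal and vertical runs of ones.

    ``diagonal[l]`` / ``vertical[v]`` count maximal runs of exact length
    l / v (all lengths >= 1; the lmin/vmin cut is applied by the feature
    formulas, not here).
    """

    diagonal: dict[int, int]
    vertical: dict[int, int]
    lmin: int = 2
    vmin: int = 2
    # runs that span their entire diagonal/column (boundary-truncated lines,
    # e.g. the length-1 corner diagonals of a fully recurrent plot); subsets
    # of the histograms above, used by the DET/LAM boundary correction
    diagonal_full: dict[int, int] = field(default_factory=dict)
    vertical_full: dict[int, int] = field(default_factory=dict)


@dataclass
class RQAFeatures:
    """The scalar RQA statistics of one recurrence plot.

    ``trapping_time`` and ``l_mean`` are mean line lengths in matrix units;
    their ``*_norm`` variants divide by M, and ``l_max_norm`` is the longest
    diagonal line divided by M. ``degenerate`` flags plots without any
    diagonal/vertical line of qualifying length, where the affected
    statistics are reported as 0.
    """

    recurrence_rate: float
    determinism: float
    entropy: float
    trapping_time: float
    laminarity: float
    l_mean: float
    l_max_norm: float
    l_max: int = 0
    trapping_time_norm: float = 0.0
    l_mean_norm: float = 0.0
    degenerate: bool = False

    _NAMES = ("recurrence_rate", "determinism", "entropy", "trapping_time",
              "laminarity", "l_mean", "l_max_norm")

    def as_array(self) -> np.ndarray:
        """The seven headline features in fixed order."""
        return np.array([getattr(self, k) for k in self._NAMES])

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self._NAMES}


def embed(samples: np.ndarray, config: EmbeddingConfig | None = None) -> PhaseTrajectory:
    """Delay-embed a scalar series into phase space."""
    config = config or EmbeddingConfig()
    x = np.asarray(samples, dtype=np.float64)
    if x.ndim != 1:
        raise ParameterError("samples must be one-dimensional")
    m, tau = config.m, config.tau
    n_vec = x.size - (m - 1) * tau
    if n_vec < 1:
        raise ParameterError(
            f"signal of length {x.size} too short for m={m}, tau={tau}"
        )
    cols = [x[j * tau: j * tau + n_vec] for j in range(m)]
    return PhaseTrajectory(points=np.column_stack(cols), config=config)


def recurrence_matrix(
    traj: PhaseTrajectory, eps_fraction: float | None = None
) -> RecurrenceMatrix:
    """Threshold pairwise Euclidean distances at a fraction of their maximum."""
    frac = traj.config.eps_fraction if eps_fraction is None else eps_fraction
    if not 0 < frac <= 1:
        raise ParameterError("eps_fraction must be in (0, 1]")
    pts = traj.points
    if pts.shape[0] == 1:
        return RecurrenceMatrix(np.ones((1, 1), dtype=bool), 0.0,
                                traj.config)
    d = pdist(pts)
    dmax = d.max()
    if dmax == 0.0:
        raise DegenerateSignalError("all trajectory points coincide")
    eps = frac * dmax
    r = squareform(d < eps)
    np.fill_diagonal(r, True)
    return RecurrenceMatrix(matrix=r, eps=float(eps), config=traj.config)


def _run_lengths(values: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of True in a 1-D boolean array."""
    if values.size == 0:
        return np.empty(0, dtype=np.int64)
    padded = np.concatenate([[False], values, [False]])
    changes = np.flatnonzero(padded[1:] != padded[:-1])
    return changes[1::2] - changes[::2]


def line_histograms(
    rp: RecurrenceMatrix, lmin: int = 2, vmin: int = 2, theiler: int = 0
) -> LineHistograms:
    """Histogram maximal diagonal and vertical runs of recurrence points.

    ``theiler`` excludes diagonals within that offset of the line of
    identity from the diagonal histogram (0 = include everything).
    """
    r = rp.matrix
    m = r.shape[0]
    diag: dict[int, int] = {}
    diag_full: dict[int, int] = {}
    for off in range(-(m - 1), m):
        if abs(off) < theiler:
            continue
        line = np.diagonal(r, offset=off)
        for ln in _run_lengths(line):
            diag[int(ln)] = diag.get(int(ln), 0) + 1
            if ln == line.size:
                diag_full[int(ln)] = diag_full.get(int(ln), 0) + 1
    vert: dict[int, int] = {}
    vert_full: dict[int, int] = {}
    for col in range(m):
        for ln in _run_lengths(r[:, col]):
            vert[int(ln)] = vert.get(int(ln), 0) + 1
            if ln == m:
                vert_full[int(ln)] = vert_full.get(int(ln), 0) + 1
    return LineHistograms(diagonal=diag, vertical=vert, lmin=lmin, vmin=vmin,
                          diagonal_full=diag_full, vertical_full=vert_full)


def _moments(hist: dict[int, int], minlen: int) -> tuple[float, float, int]:
    """(sum l*p(l), sum p(l), max l) over lengths >= minlen."""
    tot = wtot = 0
    lmax = 0
    for length, count in hist.items():
        if length >= minlen:
            tot += count
            wtot += length * count
            lmax = max(lmax, length)
    return float(wtot), float(tot), lmax


def rqa_features(
    rp: RecurrenceMatrix, lmin: int = 2, vmin: int = 2, theiler: int = 0
) -> RQAFeatures:
    """Compute the RQA statistic set from one recurrence matrix.

    DET and LAM count recurrence points lying on lines of qualifying length,
    with a boundary correction: a run that spans its entire (truncated)
    diagonal or column counts as a line even when shorter than lmin/vmin,
    since no longer line can exist there. Hence a fully recurrent plot has
    DET = LAM = 1 exactly. ENTR and Lmean use the uncorrected l >= lmin
    distribution.
    """
    hists = line_histograms(rp, lmin=lmin, vmin=vmin, theiler=theiler)
    m = rp.size
    n_rec = rp.recurrence_count
    rec = n_rec / m**2

    dw, dn, l_max = _moments(hists.diagonal, lmin)
    vw, vn, _ = _moments(hists.vertical, vmin)
    degenerate = dn == 0 or vn == 0

    dw_det = dw + sum(length * c for length, c in hists.diagonal_full.items()
                      if length < lmin)
    vw_lam = vw + sum(length * c for length, c in hists.vertical_full.items()
                      if length < vmin)
    det = dw_det / n_rec if n_rec else 0.0
    lam = vw_lam / n_rec if n_rec else 0.0
    l_mean = dw / dn if dn else 0.0
    tt = vw / vn if vn else 0.0

    entr = 0.0
    if dn:
        counts = np.array([c for length, c in hists.diagonal.items() if length >= lmin],
                          dtype=np.float64)
        p = counts / counts.sum()
        entr = float(-(p * np.log(p)).sum())

    return RQAFeatures(
        recurrence_rate=rec,
        determinism=det,
        entropy=entr,
        trapping_time=tt,
        laminarity=lam,
        l_mean=l_mean,
        l_max_norm=l_max / m,
        l_max=l_max,
        trapping_time_norm=tt / m,
        l_mean_norm=l_mean / m,
        degenerate=degenerate,
    )


def rp_to_image(rp: RecurrenceMatrix | np.ndarray, size: int = 224) -> np.ndarray:
    """Pool a recurrence matrix into a size x size density image in [0, 1].

    Rows/columns are partitioned into ``size`` contiguous, nearly equal
    blocks and each output pixel is the mean recurrence within its block
    (exactly mean-preserving when M is a multiple of ``size``). A matrix no
    larger than ``size`` is zero-padded into the top-left corner unscaled.
    """
    if size < 8:
        raise ParameterError("output size must be >= 8")
    r = rp.matrix if isinstance(rp, RecurrenceMatrix) else np.asarray(rp)
    m = r.shape[0]
    if m <= size:
        out = np.zeros((size, size))
        out[:m, :m] = r
        return out
    bounds = np.linspace(0, m, size + 1).round().astype(int)
    csum = np.zeros((m + 1, m + 1))
    csum[1:, 1:] = np.cumsum(np.cumsum(r, axis=0), axis=1)
    lo, hi = bounds[:-1], bounds[1:]
    block = (csum[np.ix_(hi, hi)] - csum[np.ix_(lo, hi)]
             - csum[np.ix_(hi, lo)] + csum[np.ix_(lo, lo)])
    areas = np.outer(hi - lo, hi - lo)
    return block / areas
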