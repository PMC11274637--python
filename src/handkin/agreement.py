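"""Between-device agreement: DTW distance, Lin's CCC, Fleiss grading.

Dynamic time warping aligns two angle traces by a monotone warping of the
frame indices minimising the cumulative elementwise cost

    d(m, n) = C(a_m, b_n) + min{d(m-1, n), d(m, n-1), d(m-1, n-1)}

with d(0, 0) = 0 and d(m, 0) = d(0, n) = infinity, so the reported distance
is D(A, B) = d(M, N).  The elementwise cost C is the absolute difference
(the Euclidean distance for scalars).  DTW absorbs temporal stretch and
shift but still penalises amplitude offsets.

Lin's concordance correlation coefficient on time-aligned pairs,

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2),

factors as CCC = r x C_b: Pearson's r measures precision and the bias
correction factor C_b in (0, 1] measures how far the best-fit line sits
from the identity.  CCC values are graded on the conventional Fleiss
bands (very good > 0.9 down to no agreement <= 0.3).

Because the two devices share a 90-degree observable range, both traces are
divided by 90 before DTW and the raw distance is divided by the warp-path
length, giving a dimensionless per-step distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import JointAngleSeries

#: Common observable range of motion used to normalise before DTW (degrees).
ROM_NORM_DEG = 90.0

FLEISS_BANDS = (
    (0.9, "very good"),
    (0.7, "acceptable"),
    (0.5, "moderate"),
    (0.3, "poor"),
    (-1.0, "no agreement"),
)


class AgreementError(ValueError):
    pass


@dataclass(frozen=True)
class WarpPath:
    """Monotone index alignment of two series (1-based pairs).

    Starts at (1, 1), ends at (M, N); each step increments m, n, or both
    by exactly one.
    """

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise AgreementError("empty warp path")
        if self.pairs[0] != (1, 1):
            raise AgreementError("warp path must start at (1, 1)")
        for (m0, n0), (m1, n1) in zip(self.pairs, self.pairs[1:]):
            if (m1 - m0, n1 - n0) not in {(1, 0), (0, 1), (1, 1)}:
                raise AgreementError(f"invalid warp step {(m0, n0)} -> {(m1, n1)}")

    def __len__(self) -> int:
        return len(self.pairs)


def dtw_distance(a: Sequence[float], b: Sequence[float]) -> tuple[float, WarpPath]:
    """Raw DTW distance and an optimal warp path (dynamic programming).

    Cost is the absolute difference per aligned pair; ties between
    predecessors break toward the diagonal, then toward advancing ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise AgreementError("DTW inputs must be non-empty")
    m, n = a.size, b.size
    cost = np.abs(a[:, None] - b[None, :])
    acc = np.full((m + 1, n + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, m + 1):
        row = acc[i]
        prev = acc[i - 1]
        ci = cost[i - 1]
        for j in range(1, n + 1):
            row[j] = ci[j - 1] + min(prev[j - 1], prev[j], row[j - 1])
    # backtrack, preferring the diagonal on ties
    pairs = [(m, n)]
    i, j = m, n
    while (i, j) != (1, 1):
        if i == 1:
            j -= 1
        elif j == 1:
            i -= 1
        else:
            diag, up, left = acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1]
            best = min(diag, up, left)
            if diag == best:
                i, j = i - 1, j - 1
            elif up == best:
                i -= 1
            else:
                j -= 1
        pairs.append((i, j))
    pairs.reverse()
    return float(acc[m, n]), WarpPath(tuple(pairs))


def dtw_bruteforce(a: Sequence[float], b: Sequence[float]) -> float:
    """Minimum path cost by exhaustive enumeration of all warping paths.

    Test oracle for tiny instances (M x N <= 64); independent of the
    dynamic program above.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    m, n = a.size, b.size
    if m == 0 or n == 0:
        raise AgreementError("DTW inputs must be non-empty")
    if m * n > 64:
        raise AgreementError("brute-force oracle limited to M x N <= 64")

    best = [np.inf]

    def walk(i: int, j: int, total: float) -> None:
        total += abs(a[i] - b[j])
        if total >= best[0]:
            return
        if i == m - 1 and j == n - 1:
            best[0] = total
            return
        if i + 1 < m and j + 1 < n:
            walk(i + 1, j + 1, total)
        if i + 1 < m:
            walk(i + 1, j, total)
        if j + 1 < n:
            walk(i, j + 1, total)

    walk(0, 0, 0.0)
    return float(best[0])


def lins_ccc(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Lin's concordance correlation on paired samples.

    Uses population (1/n) moments, per Lin's original definition.  Returns
    ``(ccc, pearson_r, c_b)`` with ``ccc = pearson_r x c_b``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise AgreementError("paired samples must have equal length")
    if x.size < 3:
        raise AgreementError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AgreementError("degenerate variance: constant input")
    mx, my = x.mean(), y.mean()
    vx = float(np.mean((x - mx) ** 2))
    vy = float(np.mean((y - my) ** 2))
    sxy = float(np.mean((x - mx) * (y - my)))
    ccc = 2.0 * sxy / (vx + vy + (mx - my) ** 2)
    pearson = sxy / np.sqrt(vx * vy)
    c_b = ccc / pearson if pearson != 0 else float("nan")
    return float(ccc), float(pearson), float(c_b)


def grade_agreement(ccc: float) -> str:
    """Fleiss band for a CCC value.

    Bands are closed contiguously as very good (0.9, 1], acceptable
    (0.7, 0.9], moderate (0.5, 0.7], poor (0.3, 0.5], no agreement
    [-1, 0.3] — the unique half-open partition consistent with the
    conventional thresholds.
    """
    if not -1.0 - 1e-12 <= ccc <= 1.0 + 1e-12:
        raise AgreementError(f"CCC {ccc} outside [-1, 1]")
    for lo, label in FLEISS_BANDS:
        if ccc > lo:
            return label
    return "no agreement"


GRADE_ORDER = {label: i for i, (_, label) in enumerate(reversed(FLEISS_BANDS))}


@dataclass
class AgreementResult:
    """Agreement of one paired subject-finger channel across devices."""

    subject_id: str
    stage: str
    finger: str
    dtw_distance: float
    dtw_raw: float
    warp_path: WarpPath
    ccc: float
    pearson_r: float
    c_b: float
    grade: str

    def as_row(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "stage": self.stage,
            "finger": self.finger,
            "dtw_distance": self.dtw_distance,
            "dtw_raw": self.dtw_raw,
            "ccc": self.ccc,
            "pearson_r": self.pearson_r,
            "c_b": self.c_b,
            "grade": self.grade,
        }


def _resample_to(series: JointAngleSeries, fps: float, n: int) -> np.ndarray:
    """Linear resampling of a series onto an ``n``-frame grid at ``fps``."""
    t_new = np.arange(n) / fps
    return np.interp(t_new, series.times, series.angles)


def compare_subject(
    a: JointAngleSeries,
    b: JointAngleSeries,
    *,
    common_fps: float = 30.0,
    ccc_pairing: str = "resample",
) -> AgreementResult:
    """Full between-device agreement for one subject-finger channel.

    Both (already preprocessed and windowed) series are normalised by the
    common 90-degree ROM; DTW runs on the normalised traces and the raw
    distance is divided by the warp-path length.  For the CCC the series
    are linearly resampled to a shared ``common_fps`` time base and paired
    frame-by-frame (``ccc_pairing="warp"`` instead pairs along the DTW
    path).
    """
    if a.finger != b.finger:
        raise AgreementError(f"finger mismatch: {a.finger} vs {b.finger}")
    if ccc_pairing not in ("resample", "warp"):
        raise AgreementError("ccc_pairing must be 'resample' or 'warp'")
    dur = min(len(a) / a.fps, len(b) / b.fps)
    if dur <= 0:
        raise AgreementError("windows do not overlap")
    n = int(round(dur * common_fps))
    xa = _resample_to(a, common_fps, n)
    xb = _resample_to(b, common_fps, n)

    raw, path = dtw_distance(xa / ROM_NORM_DEG, xb / ROM_NORM_DEG)
    norm = raw / len(path)

    if ccc_pairing == "warp":
        mi = np.array([p[0] - 1 for p in path.pairs])
        ni = np.array([p[1] - 1 for p in path.pairs])
        ccc, pearson, c_b = lins_ccc(xa[mi], xb[ni])
    else:
        ccc, pearson, c_b = lins_ccc(xa, xb)
    return AgreementResult(
        subject_id=a.subject_id,
        stage=a.stage,
        finger=a.finger,
        dtw_distance=norm,
        dtw_raw=raw,
        warp_path=path,
        ccc=ccc,
        pearson_r=pearson,
        c_b=c_b,
        grade=grade_agreement(ccc),
    )
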