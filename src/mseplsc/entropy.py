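"""Multiscale entropy: coarse-graining, sample entropy, feature matrices.

Sample entropy SampEn(m, r) of a series is -ln(A/B), where B counts pairs of
distinct length-m templates whose Chebyshev distance is strictly below the
tolerance r, A is the same count for length-(m+1) templates, and both counts
run over the same N - m template start positions (so A/B is the conditional
probability that an m-point match extends one point further). The
multiscale curve evaluates SampEn on coarse-grained versions of the signal
(non-overlapping window means of width tau), tau = 1..tau_max. The analysis
feature per subject and channel is the mean of the curve over all scales.

The pair counting is box-assisted rather than naive: templates are sorted by
their first coordinate so only candidate pairs within the tolerance on that
coordinate are examined. Counts (and hence entropies) are bit-identical to a
full O(N^2) scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from numba import njit

from .errors import DegenerateSignalError, SubjectRejectedError, ValidationError
from .io import CONDITIONS, GROUPS, EEGRecording


@dataclass(frozen=True)
class MSEParams:
    """Parameters of the multiscale sample-entropy analysis.

    m : template length (points of history used to predict the next point).
    r_factor : tolerance as a fraction of the series' standard deviation.
    tau_max : largest coarse-graining scale.
    r_mode : 'per_scale' recomputes r from each coarse-grained series' own
        standard deviation (keeps entropy exactly invariant to affine signal
        rescaling at every scale); 'scale1' fixes r from the raw series once,
        the original multiscale-entropy convention.
    """

    m: int = 2
    r_factor: float = 0.15
    tau_max: int = 20
    r_mode: Literal["per_scale", "scale1"] = "per_scale"

    def __post_init__(self):
        if self.m < 1:
            raise ValidationError(f"m must be >= 1, got {self.m}")
        if not 0 < self.r_factor < 1:
            raise ValidationError(f"r_factor must be in (0, 1), got {self.r_factor}")
        if self.tau_max < 1:
            raise ValidationError(f"tau_max must be >= 1, got {self.tau_max}")
        if self.r_mode not in ("per_scale", "scale1"):
            raise ValidationError(f"unknown r_mode {self.r_mode!r}")


def coarse_grain(signal: np.ndarray, tau: int) -> np.ndarray:
    """Non-overlapping window means of width tau; output length floor(N/tau)."""
    x = np.asarray(signal, dtype=float)
    if tau < 1:
        raise ValidationError(f"tau must be >= 1, got {tau}")
    n = len(x)
    if tau > n:
        raise ValidationError(f"tau={tau} exceeds series length {n}")
    if tau == 1:
        return x.copy()
    k = n // tau
    return x[: k * tau].reshape(k, tau).mean(axis=1)


@njit(cache=True)
def _count_template_pairs(x, order, m, r, n_t):  # pragma: no cover - numba
    """Count similar template pairs at lengths m (B) and m+1 (A).

    Both counts run over the same n_t = N - m template start positions (the
    standard convention, which makes A/B a true conditional probability).
    order: template start indices sorted by x[start]. Similarity is strict:
    Chebyshev distance < r. Counts are over unordered pairs i<j (the A/B
    ratio is identical for ordered pairs).
    """
    b_count = 0
    a_count = 0
    for a in range(n_t):
        i = order[a]
        xi0 = x[i]
        for b in range(a + 1, n_t):
            j = order[b]
            if x[j] - xi0 >= r:
                break  # sorted on first coordinate: no later candidate matches
            ok = True
            for d in range(1, m):
                diff = x[i + d] - x[j + d]
                if diff < 0.0:
                    diff = -diff
                if diff >= r:
                    ok = False
                    break
            if not ok:
                continue
            b_count += 1
            diff = x[i + m] - x[j + m]
            if diff < 0.0:
                diff = -diff
            if diff < r:
                a_count += 1
    return a_count, b_count


def sample_entropy(
    signal: np.ndarray,
    m: int = 2,
    r_factor: float = 0.15,
    r: float | None = None,
) -> float:
    """SampEn(m, r) with strict Chebyshev matching and self-matches excluded.

    The tolerance defaults to ``r_factor * std(signal)`` (population standard
    deviation); pass ``r`` to fix it explicitly. Returns NaN (an explicit
    undefined marker) when no template pair matches at either length.
    """
    x = np.ascontiguousarray(signal, dtype=float)
    n = len(x)
    if n < m + 2:
        raise ValidationError(f"series length {n} too short for m={m} (need >= m+2)")
    if r is None:
        sd = x.std()
        if sd == 0:
            raise DegenerateSignalError(
                "zero-variance signal: tolerance r = r_factor * sd would be 0"
            )
        r = r_factor * sd
    n_t = n - m  # template starts compared at both lengths m and m+1
    starts = np.arange(n_t)
    order = starts[np.argsort(x[starts], kind="stable")].astype(np.int64)
    a_count, b_count = _count_template_pairs(x, order, m, float(r), n_t)
    if a_count == 0 or b_count == 0:
        return float("nan")
    return -np.log(a_count / b_count)


def mse_curve(signal: np.ndarray, params: MSEParams = MSEParams()) -> np.ndarray:
    """Sample entropy at scales 1..tau_max; NaN marks undefined scales.

    With ``r_mode='per_scale'`` the tolerance is recomputed from each
    coarse-grained series' own standard deviation.
    """
    x = np.asarray(signal, dtype=float)
    if len(x) // params.tau_max < params.m + 2:
        raise ValidationError(
            f"series length {len(x)} leaves fewer than m+2 points at tau={params.tau_max}"
        )
    fixed_r = None
    if params.r_mode == "scale1":
        sd = x.std()
        if sd == 0:
            raise DegenerateSignalError("zero-variance signal")
        fixed_r = params.r_factor * sd
    out = np.empty(params.tau_max)
    for tau in range(1, params.tau_max + 1):
        y = coarse_grain(x, tau)
        out[tau - 1] = sample_entropy(y, params.m, params.r_factor, r=fixed_r)
    return out


@dataclass
class MSEProfile:
    """Per-channel entropy-by-scale curve for one subject/condition."""

    subject_id: str
    channel: str
    condition: str
    entropies: np.ndarray

    @property
    def has_undefined(self) -> bool:
        return bool(np.isnan(self.entropies).any())


@dataclass
class FeatureMatrix:
    """Subjects x channels block of scale-averaged entropies for one condition.

    Rows are group-contiguous (ASD, then ADHD, then CONTROL), columns follow
    the montage order; ``groups`` carries the per-row group label.
    """

    data: pd.DataFrame
    groups: pd.Series
    condition: str
    params: MSEParams

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)


def _sorted_recordings(
    recordings: Iterable[EEGRecording], condition: str
) -> list[EEGRecording]:
    recs = [r for r in recordings if r.condition == condition]
    group_rank = {g: i for i, g in enumerate(GROUPS)}
    recs.sort(key=lambda r: (group_rank[r.group], r.subject_id))
    return recs


def mse_profiles(
    recordings: Iterable[EEGRecording],
    condition: str,
    params: MSEParams = MSEParams(),
) -> list[MSEProfile]:
    """Full entropy-by-scale curves for every subject/channel of a condition."""
    profiles = []
    for rec in _sorted_recordings(recordings, condition):
        for ch in rec.montage.channels:
            curve = mse_curve(rec.channel(ch), params)
            profiles.append(MSEProfile(rec.subject_id, ch, condition, curve))
    return profiles


def feature_matrix(
    recordings: Iterable[EEGRecording],
    condition: str,
    params: MSEParams = MSEParams(),
) -> FeatureMatrix:
    """Scale-averaged entropy per subject and channel for one condition.

    A subject with an undefined entropy at any scale/channel is rejected with
    :class:`SubjectRejectedError` (no imputation).
    """
    if condition not in CONDITIONS:
        raise ValidationError(f"unknown condition {condition!r}")
    recs = _sorted_recordings(recordings, condition)
    if not recs:
        raise ValidationError(f"no recordings for condition {condition!r}")
    rows, groups, index = [], [], []
    for rec in recs:
        feats = np.empty(len(rec.montage))
        for j, ch in enumerate(rec.montage.channels):
            curve = mse_curve(rec.channel(ch), params)
            if np.isnan(curve).any():
                raise SubjectRejectedError(
                    f"subject {rec.subject_id} channel {ch}: undefined entropy "
                    f"at scales {list(np.flatnonzero(np.isnan(curve)) + 1)}"
                )
            feats[j] = curve.mean()
        rows.append(feats)
        groups.append(rec.group)
        index.append(rec.subject_id)
    data = pd.DataFrame(
        np.vstack(rows), index=pd.Index(index, name="subject_id"),
        columns=list(recs[0].montage.channels),
    )
    return FeatureMatrix(data, pd.Series(groups, index=data.index, name="group"),
                         condition, params)
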