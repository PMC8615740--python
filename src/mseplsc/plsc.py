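"""Behavior PLS correlation: grouped normalization, stacked correlation
matrix, SVD saliences, latent scores, inertia and permutation inference.

The two blocks are a subjects x channels feature matrix X (scale-averaged
entropies) and a subjects x 3 behavior matrix Y (age, mean emotional state,
confidence). Both are centered and scaled to unit column sum-of-squares
independently within each diagnostic group, so the per-group cross-product
R_n = Z_Y,n' Z_X,n is a matrix of Pearson correlations. The group blocks are
stacked (group-major; behavior rows ordered age, emotional_state, confidence)
and the stack is decomposed by SVD, R = U D V'. Columns of V ("brain
saliences") weight channels; rows of U weight group-by-behavior combinations.
Brain scores are L_X = Z_X V; behavior scores are computed per group,
L_Y,n = Z_Y,n U_n, and concatenated. The global association index is the
inertia, the sum of singular values, tested by permuting the rows of X.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .entropy import FeatureMatrix
from .errors import (
    AlignmentError,
    DegenerateColumnError,
    ValidationError,
)
from .io import SubjectBehavior

BEHAVIOR_MEASURES = ("age", "emotional_state", "confidence")
SAM_DIMENSIONS = ("valence", "arousal", "dominance")


@dataclass(frozen=True)
class GroupedDesign:
    """Group label per row of the aligned X/Y blocks (group-contiguous)."""

    labels: tuple[str, ...]

    def __post_init__(self):
        seen: list[str] = []
        for g in self.labels:
            if not seen or seen[-1] != g:
                if g in seen:
                    raise ValidationError(
                        f"rows are not group-contiguous (group {g!r} re-appears)"
                    )
                seen.append(g)
        if not seen:
            raise ValidationError("design has no rows")
        for g in seen:
            if self.labels.count(g) < 2:
                raise ValidationError(f"group {g!r} has fewer than 2 rows")
        object.__setattr__(self, "_groups", tuple(seen))

    @property
    def groups(self) -> tuple[str, ...]:
        return self._groups  # type: ignore[attr-defined]

    @property
    def n_rows(self) -> int:
        return len(self.labels)

    def block(self, group: str) -> slice:
        idx = [i for i, g in enumerate(self.labels) if g == group]
        return slice(idx[0], idx[-1] + 1)

    def blocks(self) -> list[tuple[str, slice]]:
        return [(g, self.block(g)) for g in self.groups]


def emotional_state_mean(
    row: SubjectBehavior, subset: Sequence[str] = SAM_DIMENSIONS
) -> float:
    """Arithmetic mean of the subject's SAM dimensions (configurable subset)."""
    vals = []
    for dim in subset:
        if dim not in SAM_DIMENSIONS:
            raise ValidationError(f"unknown SAM dimension {dim!r}")
        vals.append(getattr(row, f"sam_{dim}"))
    return float(np.mean(vals))


def behavior_matrix(
    rows: Iterable[SubjectBehavior],
    condition: str,
    subjects: Sequence[str],
    sam_subset: Sequence[str] = SAM_DIMENSIONS,
) -> pd.DataFrame:
    """Subjects x (age, emotional_state, confidence) block aligned to ``subjects``."""
    by_subject = {}
    for r in rows:
        if r.condition != condition:
            continue
        if r.subject_id in by_subject:
            raise ValidationError(
                f"duplicate behavior row for ({r.subject_id}, {condition})"
            )
        by_subject[r.subject_id] = r
    missing = [s for s in subjects if s not in by_subject]
    if missing:
        raise AlignmentError(f"behavior rows missing for subjects {missing}")
    data = [
        (by_subject[s].age,
         emotional_state_mean(by_subject[s], sam_subset),
         by_subject[s].confidence_percent)
        for s in subjects
    ]
    return pd.DataFrame(
        data, index=pd.Index(subjects, name="subject_id"),
        columns=list(BEHAVIOR_MEASURES),
    )


def normalize_within_group(M: np.ndarray, design: GroupedDesign) -> np.ndarray:
    """Center each column and scale it to unit sum of squares within each group."""
    M = np.asarray(M, dtype=float)
    if M.shape[0] != design.n_rows:
        raise AlignmentError(
            f"matrix has {M.shape[0]} rows but design has {design.n_rows}"
        )
    Z = np.empty_like(M)
    for g, sl in design.blocks():
        block = M[sl] - M[sl].mean(axis=0)
        ss = np.sqrt((block ** 2).sum(axis=0))
        bad = np.flatnonzero(ss == 0)
        if bad.size:
            raise DegenerateColumnError(
                f"column(s) {list(bad)} constant within group {g!r}"
            )
        Z[sl] = block / ss
    return Z


def build_correlation_matrix(
    Z_X: np.ndarray, Z_Y: np.ndarray, design: GroupedDesign
) -> np.ndarray:
    """Stack per-group correlation blocks R_n = Z_Y,n' Z_X,n (group-major rows)."""
    Z_X = np.asarray(Z_X, float)
    Z_Y = np.asarray(Z_Y, float)
    if Z_X.shape[0] != Z_Y.shape[0] or Z_X.shape[0] != design.n_rows:
        raise AlignmentError(
            f"row mismatch: X {Z_X.shape[0]}, Y {Z_Y.shape[0]}, design {design.n_rows}"
        )
    return np.vstack([Z_Y[sl].T @ Z_X[sl] for _, sl in design.blocks()])


@dataclass
class PLSCDecomposition:
    """SVD of the stacked correlation matrix with variance bookkeeping."""

    R: np.ndarray
    U: np.ndarray
    singular_values: np.ndarray
    V: np.ndarray  # columns-of-R side, shape J x L
    explained_variance: np.ndarray  # percent per component
    cumulative_variance: np.ndarray
    inertia: float  # sum of singular values
    row_labels: list | None = None
    col_labels: list | None = None

    @property
    def rank(self) -> int:
        return len(self.singular_values)

    def singular_value_table(self) -> pd.DataFrame:
        """Singular values, squares, percent and cumulative percent of variance."""
        return pd.DataFrame({
            "singular_value": self.singular_values,
            "squared": self.singular_values ** 2,
            "percent_variance": self.explained_variance,
            "cumulative_percent": self.cumulative_variance,
        }, index=pd.RangeIndex(1, self.rank + 1, name="component"))


def explained_variance_percent(squared_singular_values: Sequence[float]) -> np.ndarray:
    """Percent of total variance per component from squared singular values."""
    sq = np.asarray(squared_singular_values, float)
    return 100.0 * sq / sq.sum()


def decompose(
    R: np.ndarray,
    row_labels: list | None = None,
    col_labels: list | None = None,
    drop_tol: float = 1e-12,
) -> PLSCDecomposition:
    """Thin SVD of R with a canonical sign convention.

    Components with singular value below ``drop_tol`` times the largest are
    dropped. Each V column's largest-magnitude entry is made positive (the
    paired U column is flipped with it), fixing the SVD sign indeterminacy.
    """
    R = np.asarray(R, dtype=float)
    if not np.isfinite(R).all():
        raise ValidationError("R contains non-finite entries")
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    keep = s > (drop_tol * s[0] if s[0] > 0 else 0)
    U, s, V = U[:, keep], s[keep], Vt[keep].T
    for l in range(len(s)):
        j = np.argmax(np.abs(V[:, l]))
        if V[j, l] < 0:
            V[:, l] = -V[:, l]
            U[:, l] = -U[:, l]
    ev = explained_variance_percent(s ** 2)
    return PLSCDecomposition(
        R=R, U=U, singular_values=s, V=V,
        explained_variance=ev, cumulative_variance=np.cumsum(ev),
        inertia=float(s.sum()), row_labels=row_labels, col_labels=col_labels,
    )


def brain_scores(Z_X: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Project the normalized feature block onto the brain saliences: L_X = Z_X V."""
    Z_X = np.asarray(Z_X, float)
    V = np.asarray(V, float)
    if Z_X.shape[1] != V.shape[0]:
        raise AlignmentError(
            f"Z_X has {Z_X.shape[1]} columns but V has {V.shape[0]} rows"
        )
    return Z_X @ V


def behavior_scores(
    Z_Y: np.ndarray, U: np.ndarray, design: GroupedDesign
) -> np.ndarray:
    """Group-wise projection L_Y,n = Z_Y,n U_n, concatenated in group order.

    U's rows are stacked group-major: group n owns rows n*K..(n+1)*K-1 where
    K is the number of behavior measures.
    """
    Z_Y = np.asarray(Z_Y, float)
    k = Z_Y.shape[1]
    n_groups = len(design.groups)
    if U.shape[0] != n_groups * k:
        raise AlignmentError(
            f"U has {U.shape[0]} rows; expected {n_groups} groups x {k} measures"
        )
    out = np.empty((design.n_rows, U.shape[1]))
    for n, (_, sl) in enumerate(design.blocks()):
        out[sl] = Z_Y[sl] @ U[n * k:(n + 1) * k]
    return out


@dataclass
class BehaviorPLSCResult:
    """Everything the behavior PLSC run produces, with labels attached."""

    design: GroupedDesign
    Z_X: np.ndarray
    Z_Y: np.ndarray
    decomposition: PLSCDecomposition
    L_X: np.ndarray
    L_Y: np.ndarray
    subjects: list[str]
    channels: list[str]
    measures: list[str]

    @property
    def R_frame(self) -> pd.DataFrame:
        rows = pd.MultiIndex.from_tuples(
            self.decomposition.row_labels, names=["group", "measure"]
        )
        return pd.DataFrame(self.decomposition.R, index=rows, columns=self.channels)

    @property
    def V_frame(self) -> pd.DataFrame:
        d = self.decomposition
        return pd.DataFrame(
            d.V, index=pd.Index(self.channels, name="channel"),
            columns=[f"LV{l}" for l in range(1, d.rank + 1)],
        )

    @property
    def U_frame(self) -> pd.DataFrame:
        d = self.decomposition
        rows = pd.MultiIndex.from_tuples(d.row_labels, names=["group", "measure"])
        return pd.DataFrame(d.U, index=rows,
                            columns=[f"LV{l}" for l in range(1, d.rank + 1)])


def behavior_plsc(
    features: FeatureMatrix, behavior: pd.DataFrame
) -> BehaviorPLSCResult:
    """Run the full behavior-PLSC chain on aligned feature/behavior blocks."""
    if list(behavior.index) != list(features.data.index):
        raise AlignmentError("behavior rows are not aligned with the feature matrix")
    if behavior.isna().any().any():
        raise ValidationError("behavior matrix contains missing values")
    design = GroupedDesign(tuple(features.groups))
    Z_X = normalize_within_group(features.values, design)
    Z_Y = normalize_within_group(behavior.to_numpy(float), design)
    R = build_correlation_matrix(Z_X, Z_Y, design)
    row_labels = [
        (g, m) for g in design.groups for m in behavior.columns
    ]
    dec = decompose(R, row_labels=row_labels, col_labels=features.channels)
    return BehaviorPLSCResult(
        design=design, Z_X=Z_X, Z_Y=Z_Y, decomposition=dec,
        L_X=brain_scores(Z_X, dec.V),
        L_Y=behavior_scores(Z_Y, dec.U, design),
        subjects=list(features.data.index),
        channels=features.channels,
        measures=list(behavior.columns),
    )


@dataclass
class PermutationResult:
    """Null distribution of the inertia under row permutations of X."""

    observed_inertia: float
    null_inertias: np.ndarray
    p_value: float
    n_perm: int
    seed: int | None
    scope: str

    def summary(self) -> dict:
        return {
            "observed_inertia": self.observed_inertia,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "scope": self.scope,
            "null_mean": float(self.null_inertias.mean()),
            "null_q95": float(np.quantile(self.null_inertias, 0.95)),
        }


def _inertia(s: np.ndarray, mode: str) -> float:
    return float((s ** 2).sum()) if mode == "sum_squares" else float(s.sum())


def permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    design: GroupedDesign,
    n_perm: int = 10_000,
    seed: int | None = None,
    scope: Literal["within_group", "global"] = "within_group",
    inertia_mode: Literal["sum", "sum_squares"] = "sum",
) -> PermutationResult:
    """Permutation test of the total inertia.

    Rows of X are shuffled (independently within each group block by default,
    or across the whole matrix with ``scope='global'``), normalization is
    recomputed, the stacked correlation matrix rebuilt and its inertia
    recorded. p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValidationError(f"n_perm must be >= 1, got {n_perm}")
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    rng = np.random.default_rng(seed)
    Z_Y = normalize_within_group(Y, design)
    Z_X = normalize_within_group(X, design)
    R = build_correlation_matrix(Z_X, Z_Y, design)
    observed = _inertia(np.linalg.svd(R, compute_uv=False), inertia_mode)

    blocks = design.blocks()
    null = np.empty(n_perm)
    for b in range(n_perm):
        if scope == "within_group":
            # within-block shuffles commute with within-group normalization,
            # so permute the rows of the precomputed Z_X directly
            Zp = np.empty_like(Z_X)
            for _, sl in blocks:
                idx = np.arange(sl.start, sl.stop)
                Zp[sl] = Z_X[rng.permutation(idx)]
        elif scope == "global":
            Zp = normalize_within_group(X[rng.permutation(X.shape[0])], design)
        else:
            raise ValidationError(f"unknown permutation scope {scope!r}")
        Rp = build_correlation_matrix(Zp, Z_Y, design)
        null[b] = _inertia(np.linalg.svd(Rp, compute_uv=False), inertia_mode)

    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return PermutationResult(
        observed_inertia=observed, null_inertias=null, p_value=p,
        n_perm=n_perm, seed=seed, scope=scope,
    )
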