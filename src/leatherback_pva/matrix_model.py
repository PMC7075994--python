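"""Stage-structured annual projection matrix for the two subpopulations.

Eight life stages per subpopulation (yearling Y, juvenile I1, subadult I2,
Breeder, at-sea 2/3/4+ remigration stages, and a Transient stage for females
that breed once and are never seen again), sixteen named stages in all.  The
census is pre-breeding and female-only, so first-year survival is absorbed
into the fertility coefficient ``F = H * S1`` and the Y stage holds the
age-1 cohort.

Multi-year stages (I1: 2 yr, I2: 9 yr) are handled by one of two duration
rules:

* ``"age_expanded"`` (default): each year of a multi-year stage is its own
  matrix class (17 classes per block, 34 in all), giving a fixed stage
  duration.  This rule reproduces the published internal calibration of
  juvenile survival (S2 = 0.500 holds the population stationary when adult
  survival exceeds 0.90).
* ``"geometric"``: one class per stage (16 x 16 matrix) with stay
  probability ``S * (1 - 1/d)`` and advance probability ``S / d``.

The two subpopulation blocks are uncoupled; Nicaragua's nesting share is
folded into the Costa Rica block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .vital_rates import (
    SubpopulationSet,
    VitalRates,
    effective_fertility,
    hatchlings_to_water,
)

__all__ = [
    "STAGE_NAMES",
    "StageScheme",
    "ProjectionMatrix",
    "PopulationVector",
    "build_projection_matrix",
    "deterministic_lambda",
    "stable_stage_distribution",
    "mixture_ssd",
    "late_stage_abundance",
]

STAGE_NAMES = ("Y", "I1", "I2", "B", "A2", "A3", "A4", "T")
STAGE_DURATIONS = {"Y": 1, "I1": 2, "I2": 9, "B": 1, "A2": 1, "A3": 1, "A4": 1, "T": 1}
#: stages counted as subadult + adult ("late-stage") females
LATE_STAGES = ("I2", "B", "A2", "A3", "A4", "T")
BLOCKS = ("costa_rica", "mexico")


@dataclass(frozen=True)
class StageScheme:
    """Stage labelling and durations for one duration rule."""

    duration_rule: str
    durations: dict[str, int] = field(default_factory=lambda: dict(STAGE_DURATIONS))

    def __post_init__(self):
        if any(d < 1 for d in self.durations.values()):
            raise ValueError("stage durations must be positive integers")

    @property
    def classes_per_block(self) -> int:
        if self.duration_rule == "age_expanded":
            return sum(self.durations.values())
        return len(STAGE_NAMES)

    def block_stage_of_class(self) -> np.ndarray:
        """Stage index (0..7) of each matrix class within one block."""
        if self.duration_rule == "geometric":
            return np.arange(len(STAGE_NAMES))
        out = []
        for i, s in enumerate(STAGE_NAMES):
            out.extend([i] * self.durations[s])
        return np.array(out)

    def class_labels(self) -> list[str]:
        if self.duration_rule == "geometric":
            return list(STAGE_NAMES)
        labels = []
        for s in STAGE_NAMES:
            d = self.durations[s]
            labels.extend([s] if d == 1 else [f"{s}.{k + 1}" for k in range(d)])
        return labels


def _block_params(rates: VitalRates) -> dict[str, float]:
    h = hatchlings_to_water(rates, female_only=True)
    return {
        "F": effective_fertility(h, rates.s1),
        "S2": rates.s2,
        "S3": rates.s3,
        "B1": rates.b1,
        "B2": rates.b2,
        "B3": rates.b3,
        "B4": rates.b4,
        "Tr": rates.transient,
    }


def assemble_block(params: dict[str, np.ndarray], duration_rule: str = "age_expanded") -> np.ndarray:
    """Batched assembly of one subpopulation block.

    ``params`` maps F/S2/S3/B1..B4/Tr to arrays of shape ``(n,)``; returns
    ``(n, C, C)``.  Both the Breeder and Transient columns carry the
    fertility coefficient (a transient breeds in her single nesting season
    and then leaves the modelled population).
    """
    arrs = {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in params.items()}
    n = max(a.shape[0] for a in arrs.values())
    arrs = {k: np.broadcast_to(a, (n,)) for k, a in arrs.items()}
    S2, S3, Tr, F = arrs["S2"], arrs["S3"], arrs["Tr"], arrs["F"]
    B = [arrs["B1"], arrs["B2"], arrs["B3"], arrs["B4"]]
    for k in ("S2", "S3", "Tr", "B1", "B2", "B3", "B4"):
        if np.any(arrs[k] > 1.0 + 1e-12) or np.any(arrs[k] < 0):
            raise ValueError(f"transition parameter {k} outside [0, 1]")

    scheme = StageScheme(duration_rule)
    C = scheme.classes_per_block
    A = np.zeros((n, C, C))
    if duration_rule == "age_expanded":
        d1, d2 = scheme.durations["I1"], scheme.durations["I2"]
        iB = 1 + d1 + d2
        iT = C - 1
        # juvenile survival on Y and I1 classes, subadult survival within I2
        for k in range(1 + d1):
            A[:, k + 1, k] = S2
        for k in range(1 + d1, d1 + d2):
            A[:, k + 1, k] = S3
        last_i2 = d1 + d2
        A[:, iB, last_i2] = S3 * (1 - Tr)
        A[:, iT, last_i2] = S3 * Tr
    elif duration_rule == "geometric":
        d1, d2 = scheme.durations["I1"], scheme.durations["I2"]
        iB, iT = 3, C - 1
        A[:, 1, 0] = S2
        A[:, 1, 1] = S2 * (1 - 1 / d1)
        A[:, 2, 1] = S2 / d1
        A[:, 2, 2] = S3 * (1 - 1 / d2)
        A[:, iB, 2] = S3 / d2 * (1 - Tr)
        A[:, iT, 2] = S3 / d2 * Tr
    else:
        raise ValueError(f"unknown duration_rule: {duration_rule!r}")

    A[:, 0, iB] = F
    A[:, 0, iT] = F
    # remigration loop: breed the year after breeding with B1, then via the
    # at-sea 2/3/4+ stages with B2..B4; the 4+ stage pools longer intervals
    A[:, iB, iB] = S3 * B[0]
    A[:, iB + 1, iB] = S3 * (1 - B[0])
    for j in (1, 2):
        A[:, iB, iB + j] = S3 * B[j]
        A[:, iB + j + 1, iB + j] = S3 * (1 - B[j])
    A[:, iB, iB + 3] = S3 * B[3]
    A[:, iB + 3, iB + 3] = S3 * (1 - B[3])
    return A


@dataclass
class ProjectionMatrix:
    """Annual transition matrix with its stage bookkeeping.

    ``matrix`` is block-diagonal over (costa_rica, mexico); under the
    age-expanded rule it is 34 x 34 with ``stage_of_class`` aggregating the
    classes back to the 16 named stages.
    """

    matrix: np.ndarray
    scheme: StageScheme
    class_labels: list[str]
    stage_of_class: np.ndarray  # index into the 16 stage labels
    provenance: str = ""

    def __post_init__(self):
        if np.any(self.matrix < 0) or not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix entries must be finite and non-negative")
        survival = self.matrix.copy()
        survival[0] = 0.0  # fertility row of block 1
        survival[self.scheme.classes_per_block] = 0.0  # fertility row of block 2
        colsums = survival.sum(axis=0)
        if np.any(colsums > 1.0 + 1e-12):
            raise ValueError("survival-type column sums exceed 1")

    @property
    def n_classes(self) -> int:
        return self.matrix.shape[0]

    def block_slice(self, block: str) -> slice:
        C = self.scheme.classes_per_block
        i = BLOCKS.index(block)
        return slice(i * C, (i + 1) * C)

    def stage_labels(self) -> list[str]:
        return [f"{s}_{b}" for b in ("CR", "MX") for s in STAGE_NAMES]

    def stage_mask(self, stages: Iterable[str], block: str | None = None) -> np.ndarray:
        """Boolean mask over classes belonging to the given stage names."""
        want = {STAGE_NAMES.index(s) for s in stages}
        per_block = np.isin(self.scheme.block_stage_of_class(), list(want))
        mask = np.concatenate([per_block, per_block])
        if block is not None:
            keep = np.zeros_like(mask)
            keep[self.block_slice(block)] = True
            mask &= keep
        return mask

    def aggregate_stages(self, x: np.ndarray) -> np.ndarray:
        """Sum a class-level vector (.., n_classes) into the 16 stages."""
        C = self.scheme.classes_per_block
        s = self.scheme.block_stage_of_class()
        out = np.zeros(x.shape[:-1] + (16,))
        for b in range(2):
            for i in range(C):
                out[..., 8 * b + s[i]] += x[..., b * C + i]
        return out

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix, index=self.class_labels, columns=self.class_labels).to_csv(path)

    @staticmethod
    def read_csv(path: str | Path, duration_rule: str = "age_expanded") -> "ProjectionMatrix":
        df = pd.read_csv(path, index_col=0)
        scheme = StageScheme(duration_rule)
        s = scheme.block_stage_of_class()
        return ProjectionMatrix(
            matrix=df.to_numpy(dtype=float),
            scheme=scheme,
            class_labels=list(df.columns),
            stage_of_class=np.concatenate([s, s + 8]),
            provenance=f"read from {path}",
        )


def build_projection_matrix(
    params: SubpopulationSet, duration_rule: str = "age_expanded"
) -> ProjectionMatrix:
    """Build the full two-block annual projection matrix from mean rates."""
    scheme = StageScheme(duration_rule)
    C = scheme.classes_per_block
    A = np.zeros((2 * C, 2 * C))
    labels: list[str] = []
    for i, block in enumerate(BLOCKS):
        rates = getattr(params, block)
        A[i * C:(i + 1) * C, i * C:(i + 1) * C] = assemble_block(
            _block_params(rates), duration_rule
        )[0]
        suffix = {"costa_rica": "CR", "mexico": "MX"}[block]
        labels.extend(f"{lab}_{suffix}" for lab in scheme.class_labels())
    s = scheme.block_stage_of_class()
    return ProjectionMatrix(
        matrix=A,
        scheme=scheme,
        class_labels=labels,
        stage_of_class=np.concatenate([s, s + 8]),
        provenance=f"duration_rule={duration_rule}",
    )


def _as_array(A) -> np.ndarray:
    return A.matrix if isinstance(A, ProjectionMatrix) else np.asarray(A, dtype=float)


def deterministic_lambda(A) -> float:
    """Dominant eigenvalue modulus (asymptotic annual growth rate)."""
    M = _as_array(A)
    if not np.all(np.isfinite(M)):
        raise ValueError("matrix has non-finite entries")
    return float(np.max(np.abs(np.linalg.eigvals(M))))


@dataclass
class PopulationVector:
    """Per-class abundance (or proportions) tied to its matrix."""

    values: np.ndarray
    matrix: ProjectionMatrix | None = None
    year: int = 0
    unique: bool = True

    def __post_init__(self):
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("abundances must be finite and non-negative")


def stable_stage_distribution(A, atol: float = 1e-10):
    """Right eigenvector of the dominant eigenvalue, normalised to sum 1.

    Returns a :class:`PopulationVector`; ``unique`` is False when the
    dominant eigenvalue is (numerically) repeated, as for reducible
    matrices with tied blocks.
    """
    M = _as_array(A)
    vals, vecs = np.linalg.eig(M)
    order = np.argsort(-np.abs(vals))
    lam = vals[order[0]]
    unique = len(vals) < 2 or abs(abs(vals[order[0]]) - abs(vals[order[1]])) > 1e-9 * max(
        1.0, abs(lam)
    )
    w = np.real(vecs[:, order[0]])
    w = np.abs(w)
    w = w / w.sum()
    resid = np.max(np.abs(M @ w - np.real(lam) * w))
    if resid > atol * max(1.0, float(np.abs(M).max())):
        raise ValueError(f"eigenvector residual {resid:.2e} exceeds tolerance")
    pm = A if isinstance(A, ProjectionMatrix) else None
    return PopulationVector(values=w, matrix=pm, unique=unique)


def mixture_ssd(pm: ProjectionMatrix, params: SubpopulationSet) -> PopulationVector:
    """Block-wise stable stage distribution mixed by nesting shares.

    Each block's own dominant eigenvector is scaled so the block's Breeder
    abundance matches its nesting share, then the blocks are concatenated
    and renormalised.  This is the long-run composition of each
    subpopulation, weighted by observed nesting activity.
    """
    C = pm.scheme.classes_per_block
    shares = params.block_shares
    out = np.zeros(pm.n_classes)
    for block in BLOCKS:
        sl = pm.block_slice(block)
        sub = pm.matrix[sl, sl]
        w = stable_stage_distribution(sub).values
        b_mask = pm.stage_mask(["B"], block)[sl]
        out[sl] = w / w[b_mask].sum() * shares[block]
    return PopulationVector(values=out / out.sum(), matrix=pm)


def late_stage_abundance(
    ssd: PopulationVector, breeder_count: float, sex_ratio: float
) -> dict[str, float]:
    """Scale a stage distribution to the annual breeder count and sum the
    subadult + adult stages.

    Returns female and total (both-sex) late-stage abundance; the total
    assumes the operational sex ratio equals the hatchling sex ratio.
    """
    if breeder_count <= 0:
        raise ValueError("breeder_count must be positive")
    if not 0 < sex_ratio <= 1:
        raise ValueError("sex_ratio must be in (0, 1]")
    if ssd.matrix is None:
        raise ValueError("stage distribution must carry its ProjectionMatrix")
    w = ssd.values
    b = w[ssd.matrix.stage_mask(["B"])].sum()
    if b <= 0:
        raise ValueError("stage distribution has zero breeder mass")
    scale = breeder_count / b
    females = float(w[ssd.matrix.stage_mask(LATE_STAGES)].sum() * scale)
    return {"females": females, "total": females / sex_ratio}
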