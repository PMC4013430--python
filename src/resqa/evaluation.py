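"""Ground-truth local qualities and evaluation metrics.

True per-residue deviations come from a single whole-chain least-squares
CA superposition (Kabsch algorithm, proper rotation enforced) of the model
onto the native structure — a documented approximation of the
sequence-dependent superpositions used in CASP assessment.

Local predictions are scored by the absolute difference between predicted
and real deviation (overall mean and binned by real deviation rounded to
the nearest integer Å) and by per-model Pearson correlation. Global
predictions are scored per target by average/overall correlation, the mean
true quality of each target's top-ranked model, and the average ranking
loss (best true quality minus true quality of the model ranked first).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InputError
from .scoring import DEFAULT_C, local_to_global
from .structure_io import ProteinModel, extract_sequence


@dataclass
class SuperpositionResult:
    rotation: np.ndarray          # (3, 3), det = +1
    translation: np.ndarray       # (3,)
    per_residue_deviation: np.ndarray  # (L,), Å
    rmsd: float

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted rigid motion to (N, 3) coordinates."""
        return coords @ self.rotation.T + self.translation


@dataclass
class BinStat:
    real_deviation: int
    mean_abs_error: float
    count: int
    sparse: bool  # flagged when fewer than 10 points support the bin


@dataclass
class LocalEvalReport:
    mean_absolute_difference_error: float
    binned_curve: list[BinStat]
    per_model_correlation: dict[str, float | None]
    mean_correlation: float | None
    n_residues: int


@dataclass
class GlobalEvalReport:
    avg_correlation: float | None
    overall_correlation: float | None
    avg_top1_quality: float
    avg_loss: float
    n_targets: int = 0
    excluded_targets: list[str] = field(default_factory=list)


def superimpose(model: ProteinModel, native: ProteinModel) -> SuperpositionResult:
    """Least-squares CA superposition of ``model`` onto ``native``.

    Kabsch algorithm on all CA pairs; reflections are never allowed
    (det(R) = +1). Per-residue deviation is the CA–CA distance after the
    fitted transform.
    """
    if len(model) != len(native):
        raise InputError(
            f"model has {len(model)} residues but native has {len(native)}"
        )
    if extract_sequence(model) != extract_sequence(native):
        raise InputError("model and native sequences differ")
    x = model.coords("CA")
    y = native.coords("CA")
    mx, my = x.mean(axis=0), y.mean(axis=0)
    xc, yc = x - mx, y - my
    h = xc.T @ yc
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = my - rotation @ mx
    mapped = x @ rotation.T + translation
    dev = np.linalg.norm(mapped - y, axis=1)
    return SuperpositionResult(
        rotation=rotation,
        translation=translation,
        per_residue_deviation=dev,
        rmsd=float(np.sqrt(np.mean(dev**2))),
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    """Pearson r, or None when undefined (constant input or n < 2)."""
    if len(a) < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    r = stats.pearsonr(a, b).statistic
    return None if math.isnan(r) else float(r)


def local_eval(
    pred_deviations,
    real_deviations,
    model_ids=None,
) -> LocalEvalReport:
    """Score per-residue predictions against real deviations.

    ``model_ids`` (optional, one label per residue) groups residues into
    models for the per-model correlations; without it all residues form a
    single group. Constant groups have undefined correlation and are
    excluded from the mean.
    """
    pred = np.asarray(pred_deviations, dtype=float)
    real = np.asarray(real_deviations, dtype=float)
    if pred.shape != real.shape or pred.ndim != 1:
        raise InputError("prediction/truth vectors must be 1-D and equal length")
    if pred.size == 0:
        raise InputError("nothing to evaluate")
    if model_ids is None:
        model_ids = ["all"] * len(pred)
    model_ids = list(model_ids)
    if len(model_ids) != len(pred):
        raise InputError("model_ids length mismatch")

    mean_err = float(np.mean(np.abs(pred - real)))

    bins = np.floor(real + 0.5).astype(int)
    curve = []
    for b in sorted(set(bins)):
        mask = bins == b
        curve.append(
            BinStat(
                real_deviation=int(b),
                mean_abs_error=float(np.mean(np.abs(pred[mask] - real[mask]))),
                count=int(mask.sum()),
                sparse=bool(mask.sum() < 10),
            )
        )

    per_model: dict[str, float | None] = {}
    for mid in dict.fromkeys(model_ids):  # preserve first-seen order
        mask = np.array([m == mid for m in model_ids])
        per_model[str(mid)] = _pearson(pred[mask], real[mask])
    defined = [r for r in per_model.values() if r is not None]
    mean_corr = float(np.mean(defined)) if defined else None

    return LocalEvalReport(
        mean_absolute_difference_error=mean_err,
        binned_curve=curve,
        per_model_correlation=per_model,
        mean_correlation=mean_corr,
        n_residues=int(pred.size),
    )


def global_quality_true(
    model: ProteinModel, native: ProteinModel, c: float = DEFAULT_C
) -> float:
    """True global quality of a model: S-score of its real deviations."""
    sup = superimpose(model, native)
    return local_to_global(sup.per_residue_deviation, c=c)


def global_eval(per_target: dict[str, list[tuple[float, float]]]) -> GlobalEvalReport:
    """Score global predictions over targets.

    ``per_target`` maps target id -> list of (predicted, true) global
    scores, one entry per model. Reports the mean per-target Pearson
    correlation, the pooled Pearson correlation, the mean true quality of
    the model each target ranks first (ties: first index), and the mean
    loss (best true quality minus top-ranked true quality). Targets whose
    predictions are constant are excluded from the correlation averages
    but still contribute to top-1 quality and loss.
    """
    if not per_target:
        raise InputError("no targets to evaluate")
    corrs = []
    excluded = []
    top1, losses = [], []
    pooled_pred, pooled_true = [], []
    for tid, pairs in per_target.items():
        if not pairs:
            raise InputError(f"target {tid} has no models")
        pred = np.array([p for p, _ in pairs], dtype=float)
        true = np.array([t for _, t in pairs], dtype=float)
        pooled_pred.append(pred)
        pooled_true.append(true)
        if len(pairs) >= 2:
            r = _pearson(pred, true)
            if r is None:
                excluded.append(str(tid))
            else:
                corrs.append(r)
        top_idx = int(np.argmax(pred))
        top1.append(true[top_idx])
        losses.append(float(true.max() - true[top_idx]))
    overall = _pearson(np.concatenate(pooled_pred), np.concatenate(pooled_true))
    return GlobalEvalReport(
        avg_correlation=float(np.mean(corrs)) if corrs else None,
        overall_correlation=overall,
        avg_top1_quality=float(np.mean(top1)),
        avg_loss=float(np.mean(losses)),
        n_targets=len(per_target),
        excluded_targets=excluded,
    )
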