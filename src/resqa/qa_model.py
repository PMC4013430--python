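"""RBF-kernel support-vector regression of per-residue distance deviations.

The estimator follows the statsmodels convention: a
:class:`ResidueQualityModel` is constructed from a labelled
:class:`~resqa.feature_encoding.ExampleSet`; ``fit()`` runs a grid search
over (cost C, epsilon tube width, RBF gamma) with grouped 5-fold
cross-validation — all residues of one structural model stay in the same
fold, because residues of a model are strongly dependent — and returns a
:class:`ResidueQualityResults` carrying the chosen hyper-parameters, the
CV error table, prediction methods, a ``summary()`` table and
save/load. The CV objective is the mean absolute error on held-out folds,
matching the absolute-difference-error evaluation metric; ties are broken
deterministically toward the smallest (cost, epsilon, gamma).

Predicted deviations are distances and are clamped at zero from below;
``predict_local`` additionally converts them to the global S-score
(``local_to_global``) with c = 5 Å.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import joblib
import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .errors import InputError, ResqaError
from .feature_encoding import ExampleSet
from .scoring import DEFAULT_C, local_to_global

__all__ = [
    "SvrConfig",
    "LocalQualityResult",
    "ResidueQualityModel",
    "ResidueQualityResults",
    "local_to_global",
]

DEFAULT_COST_GRID = (0.1, 1.0, 10.0)
DEFAULT_EPSILON_GRID = (0.1, 0.5, 1.0)
DEFAULT_GAMMA_GRID = (0.001, 0.01, 0.1)

_MODEL_FORMAT_VERSION = 1


@dataclass
class SvrConfig:
    cost_grid: tuple = DEFAULT_COST_GRID
    epsilon_grid: tuple = DEFAULT_EPSILON_GRID
    gamma_grid: tuple = DEFAULT_GAMMA_GRID
    folds: int = 5
    seed: int = 0

    def __post_init__(self):
        for name in ("cost_grid", "epsilon_grid", "gamma_grid"):
            vals = tuple(float(v) for v in getattr(self, name))
            if not vals or any(v <= 0 for v in vals):
                raise InputError(f"{name} must be non-empty with positive values")
            setattr(self, name, vals)
        if self.folds < 2:
            raise InputError("folds must be >= 2")

    @property
    def grid(self) -> list[tuple[float, float, float]]:
        """Deduplicated, deterministically ordered (cost, epsilon, gamma) triples."""
        return sorted(
            set(
                itertools.product(
                    self.cost_grid, self.epsilon_grid, self.gamma_grid
                )
            )
        )


@dataclass
class LocalQualityResult:
    """Predicted per-residue deviations (Å) and the derived global score."""

    deviations: np.ndarray
    global_score: float
    residue_ids: list[tuple[str, int]] = field(default_factory=list)
    c: float = DEFAULT_C


class ResidueQualityModel:
    """Per-residue deviation regressor, statsmodels-style.

    Parameters
    ----------
    examples : ExampleSet
        Labelled training examples (feature rows with real deviations).
    config : SvrConfig, optional
        Hyper-parameter grids, fold count and shuffle seed.
    """

    def __init__(self, examples: ExampleSet, config: SvrConfig | None = None):
        if examples.targets is None:
            raise InputError("training requires examples with targets")
        if examples.n_examples < 1:
            raise InputError("no training examples")
        self.examples = examples
        self.config = config or SvrConfig()
        if examples.n_examples < self.config.folds:
            raise InputError("fewer examples than folds")

    # ---- folds ---------------------------------------------------------

    def fold_assignment(self) -> np.ndarray:
        """Fold index per example; all rows of one model share a fold.

        Unique model ids are sorted, shuffled with the seeded generator and
        dealt round-robin over the folds, so the assignment is invariant to
        example row order.
        """
        keys = sorted({mid for mid, _ in self.examples.residue_ids})
        if len(keys) < self.config.folds:
            raise InputError(
                f"{len(keys)} model groups cannot fill {self.config.folds} folds"
            )
        rng = np.random.default_rng(self.config.seed)
        order = [keys[i] for i in rng.permutation(len(keys))]
        fold_of_key = {k: i % self.config.folds for i, k in enumerate(order)}
        return np.array(
            [fold_of_key[mid] for mid, _ in self.examples.residue_ids]
        )

    # ---- CV and fitting -------------------------------------------------

    def cross_validate(self) -> tuple[pd.DataFrame, tuple[float, float, float]]:
        """Grid search; returns the CV table and the best triple.

        The table has one row per (cost, epsilon, gamma) with the pooled
        mean absolute error over all held-out folds.
        """
        x = self.examples.features
        y = self.examples.targets
        folds = self.fold_assignment()
        rows = []
        best = None
        best_err = np.inf
        for cost, epsilon, gamma in self.config.grid:
            abs_errors = []
            for f in range(self.config.folds):
                test = folds == f
                svr = SVR(kernel="rbf", C=cost, epsilon=epsilon, gamma=gamma)
                svr.fit(x[~test], y[~test])
                abs_errors.append(np.abs(svr.predict(x[test]) - y[test]))
            err = float(np.mean(np.concatenate(abs_errors)))
            rows.append(
                {"cost": cost, "epsilon": epsilon, "gamma": gamma, "cv_mae": err}
            )
            if err < best_err:  # strict: first (smallest) triple wins ties
                best_err = err
                best = (cost, epsilon, gamma)
        return pd.DataFrame(rows), best

    def fit(
        self, params: tuple[float, float, float] | None = None
    ) -> "ResidueQualityResults":
        """Cross-validate (unless ``params`` is given) and fit on all examples."""
        cv_table = None
        if params is None:
            cv_table, params = self.cross_validate()
        cost, epsilon, gamma = params
        svr = SVR(kernel="rbf", C=cost, epsilon=epsilon, gamma=gamma)
        svr.fit(self.examples.features, self.examples.targets)
        constant = bool(np.ptp(self.examples.targets) == 0)
        return ResidueQualityResults(
            svr=svr,
            params={"cost": cost, "epsilon": epsilon, "gamma": gamma},
            cv_table=cv_table,
            feature_set=self.examples.feature_set,
            window=self.examples.window,
            dim=self.examples.dim,
            n_train=self.examples.n_examples,
            config=self.config,
            constant_target=constant,
        )


class ResidueQualityResults:
    """Fitted per-residue quality regressor."""

    def __init__(
        self,
        svr: SVR,
        params: dict,
        cv_table: pd.DataFrame | None,
        feature_set: str,
        window: int,
        dim: int,
        n_train: int,
        config: SvrConfig | None = None,
        constant_target: bool = False,
    ):
        self.svr = svr
        self.params = params
        self.cv_table = cv_table
        self.feature_set = feature_set
        self.window = window
        self.dim = dim
        self.n_train = n_train
        self.config = config
        self.constant_target = constant_target

    # ---- prediction -----------------------------------------------------

    def _check(self, examples: ExampleSet | np.ndarray) -> np.ndarray:
        if isinstance(examples, ExampleSet):
            if examples.feature_set != self.feature_set:
                raise InputError(
                    f"feature set mismatch: model is {self.feature_set!r}, "
                    f"input is {examples.feature_set!r}"
                )
            x = examples.features
        else:
            x = np.asarray(examples, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.dim:
            raise InputError(
                f"feature dimension mismatch: model expects {self.dim}, "
                f"got {x.shape[1] if x.ndim == 2 else x.shape}"
            )
        return x

    def predict(self, examples: ExampleSet | np.ndarray) -> np.ndarray:
        """Predicted per-residue deviations (Å), clamped at 0 from below."""
        x = self._check(examples)
        return np.maximum(self.svr.predict(x), 0.0)

    def predict_local(
        self, examples: ExampleSet, c: float = DEFAULT_C
    ) -> LocalQualityResult:
        """Per-residue deviations plus the derived global quality score."""
        dev = self.predict(examples)
        return LocalQualityResult(
            deviations=dev,
            global_score=local_to_global(dev, c=c),
            residue_ids=list(getattr(examples, "residue_ids", [])),
            c=c,
        )

    # ---- reporting / persistence ----------------------------------------

    def summary(self) -> str:
        lines = [
            "Residue quality regression (epsilon-SVR, RBF kernel)",
            "=" * 52,
            f"feature set:       {self.feature_set}",
            f"window:            {self.window}",
            f"feature dimension: {self.dim}",
            f"training examples: {self.n_train}",
            f"chosen cost (C):   {self.params['cost']:g}",
            f"chosen epsilon:    {self.params['epsilon']:g}",
            f"chosen gamma:      {self.params['gamma']:g}",
            f"support vectors:   {len(self.svr.support_)}",
        ]
        if self.constant_target:
            lines.append("warning: training targets were constant")
        if self.cv_table is not None:
            lines.append("")
            lines.append("Cross-validation (pooled held-out MAE, Å):")
            lines.append(self.cv_table.to_string(index=False))
        return "\n".join(lines)

    def save(self, path) -> None:
        payload = {
            "format_version": _MODEL_FORMAT_VERSION,
            "svr": self.svr,
            "params": self.params,
            "cv_table": self.cv_table,
            "feature_set": self.feature_set,
            "window": self.window,
            "dim": self.dim,
            "n_train": self.n_train,
            "config": asdict(self.config) if self.config else None,
            "constant_target": self.constant_target,
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path) -> "ResidueQualityResults":
        payload = joblib.load(path)
        if payload.get("format_version") != _MODEL_FORMAT_VERSION:
            raise ResqaError(
                f"unsupported model file version: {payload.get('format_version')}"
            )
        cfg = payload.get("config")
        return cls(
            svr=payload["svr"],
            params=payload["params"],
            cv_table=payload["cv_table"],
            feature_set=payload["feature_set"],
            window=payload["window"],
            dim=payload["dim"],
            n_train=payload["n_train"],
            config=SvrConfig(**cfg) if cfg else None,
            constant_target=payload.get("constant_target", False),
        )
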