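"""Per-residue feature vectors from model-derived and predicted annotations.

A sliding window (15 residues by default) is centred on each residue. Each
window position contributes a 23-value block, in the frozen order

    [amino-acid (20), SS-match bit, exposure-match bit, contact agreement]

where the amino-acid block is a one-hot indicator (basic feature set) or
the logistic-squashed PSSM row (profile feature sets), the match bits
compare the model-parsed secondary structure / exposure with the
sequence-based predictions, and the contact agreement is the mean
predicted contact probability over the residue's observed structural
contacts (0 when it has none). Window positions outside the chain are
all-zero blocks. The profile+SOV set appends one whole-chain SOV scalar,
identical for every residue of a model.

With the default window of 15 the dimensions are 15*23 = 345 (basic,
profile) and 346 (profile+SOV); every feature value lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._aa import AA_INDEX
from .errors import IncompleteModelError, InputError
from .model_features import ModelDerivedFeatures, derive_features
from .prediction_inputs import PredictedAnnotations
from .sov import sov_score
from .structure_io import ProteinModel, check_completeness

FEATURE_SETS = ("basic", "profile", "profile_sov")


@dataclass
class EncodingConfig:
    window: int = 15
    feature_set: str = "basic"
    contact_min_sep: int = 6
    contact_max_dist: float = 8.0
    target_cap: float | None = 15.0  # cap on training deviations, Å; None disables

    def __post_init__(self):
        if self.window < 1 or self.window % 2 == 0:
            raise InputError("window must be odd and >= 1")
        if self.feature_set not in FEATURE_SETS:
            raise InputError(f"feature_set must be one of {FEATURE_SETS}")

    @property
    def dim(self) -> int:
        d = self.window * 23
        return d + 1 if self.feature_set == "profile_sov" else d


@dataclass
class ExampleSet:
    """N per-residue feature rows with optional real-deviation targets."""

    features: np.ndarray                 # (N, D)
    targets: np.ndarray | None           # (N,) real deviations, Å
    residue_ids: list[tuple[str, int]]   # (model id, 1-based residue index)
    feature_set: str = "basic"
    window: int = 15

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        if self.targets is not None:
            self.targets = np.asarray(self.targets, dtype=float)
            if len(self.targets) != len(self.features):
                raise InputError("targets length != feature rows")
        if len(self.residue_ids) != len(self.features):
            raise InputError("residue_ids length != feature rows")

    @property
    def n_examples(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]

    @classmethod
    def concatenate(cls, sets: list["ExampleSet"]) -> "ExampleSet":
        if not sets:
            raise InputError("nothing to concatenate")
        tags = {(s.feature_set, s.window, s.dim) for s in sets}
        if len(tags) > 1:
            raise InputError(f"incompatible example sets: {tags}")
        has_targets = [s.targets is not None for s in sets]
        if any(has_targets) and not all(has_targets):
            raise InputError("cannot mix labelled and unlabelled example sets")
        return cls(
            features=np.vstack([s.features for s in sets]),
            targets=np.concatenate([s.targets for s in sets]) if all(has_targets) else None,
            residue_ids=[rid for s in sets for rid in s.residue_ids],
            feature_set=sets[0].feature_set,
            window=sets[0].window,
        )

    # ---- serialization -------------------------------------------------

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# resqa ExampleSet v1\n")
            fh.write(f"# feature_set={self.feature_set} window={self.window} "
                     f"dim={self.dim}\n")
            cols = ["model_id", "residue_index", "target"] + [
                f"f{k + 1}" for k in range(self.dim)
            ]
            fh.write("\t".join(cols) + "\n")
            for i, (mid, ridx) in enumerate(self.residue_ids):
                tgt = "NA" if self.targets is None else f"{self.targets[i]:.12g}"
                vals = "\t".join(f"{v:.12g}" for v in self.features[i])
                fh.write(f"{mid}\t{ridx}\t{tgt}\t{vals}\n")

    @classmethod
    def from_tsv(cls, path) -> "ExampleSet":
        feature_set, window = "basic", 15
        rows, targets, rids = [], [], []
        with open(path) as fh:
            header_seen = False
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    for tok in line[1:].split():
                        if tok.startswith("feature_set="):
                            feature_set = tok.split("=", 1)[1]
                        elif tok.startswith("window="):
                            window = int(tok.split("=", 1)[1])
                    continue
                if not line:
                    continue
                if not header_seen:
                    header_seen = True  # column-name row
                    continue
                tok = line.split("\t")
                rids.append((tok[0], int(tok[1])))
                targets.append(None if tok[2] == "NA" else float(tok[2]))
                rows.append([float(v) for v in tok[3:]])
        if not rows:
            raise InputError(f"no examples in {path}")
        has_t = targets[0] is not None
        if any((t is not None) != has_t for t in targets):
            raise InputError(f"mixed labelled/unlabelled rows in {path}")
        return cls(
            features=np.array(rows),
            targets=np.array(targets, dtype=float) if has_t else None,
            residue_ids=rids,
            feature_set=feature_set,
            window=window,
        )

    def to_svmlight(self, path) -> None:
        """Sparse "target idx:val" format; zero features omitted, metadata
        in comments so the round trip is lossless."""
        with open(path, "w") as fh:
            fh.write(f"# resqa ExampleSet v1 feature_set={self.feature_set} "
                     f"window={self.window} dim={self.dim} "
                     f"labelled={int(self.targets is not None)}\n")
            for i, (mid, ridx) in enumerate(self.residue_ids):
                tgt = 0.0 if self.targets is None else self.targets[i]
                pairs = " ".join(
                    f"{k + 1}:{v:.12g}"
                    for k, v in enumerate(self.features[i])
                    if v != 0.0
                )
                fh.write(f"{tgt:.12g} {pairs} # {mid} {ridx}\n")

    @classmethod
    def from_svmlight(cls, path) -> "ExampleSet":
        feature_set, window, dim, labelled = "basic", 15, None, True
        rows, targets, rids = [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    for tok in line[1:].split():
                        if "=" in tok:
                            key, val = tok.split("=", 1)
                            if key == "feature_set":
                                feature_set = val
                            elif key == "window":
                                window = int(val)
                            elif key == "dim":
                                dim = int(val)
                            elif key == "labelled":
                                labelled = bool(int(val))
                    continue
                body, _, comment = line.partition(" # ")
                tok = body.split()
                targets.append(float(tok[0]))
                ctok = comment.split()
                rids.append((ctok[0], int(ctok[1])) if len(ctok) >= 2
                            else ("unknown", len(rows) + 1))
                rows.append(tok[1:])
        if dim is None:
            raise InputError(f"missing dim header in {path}")
        feats = np.zeros((len(rows), dim))
        for i, pairs in enumerate(rows):
            for pair in pairs:
                k, v = pair.split(":")
                feats[i, int(k) - 1] = float(v)
        return cls(
            features=feats,
            targets=np.array(targets) if labelled else None,
            residue_ids=rids,
            feature_set=feature_set,
            window=window,
        )


def contact_agreement_feature(
    residue_index: int,
    contacts: list[list[int]],
    contact_prob: np.ndarray,
) -> float:
    """Mean predicted contact probability over a residue's observed contacts.

    ``residue_index`` is 1-based; returns 0.0 when the residue has no
    observed structural contacts.
    """
    if not 1 <= residue_index <= len(contacts):
        raise InputError(f"residue index {residue_index} out of range")
    partners = contacts[residue_index - 1]
    if not partners:
        return 0.0
    probs = [contact_prob[residue_index - 1, j - 1] for j in partners]
    return float(np.mean(probs))


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _position_blocks(
    model_feats: ModelDerivedFeatures,
    pred: PredictedAnnotations,
    cfg: EncodingConfig,
) -> np.ndarray:
    """(L, 23) matrix of per-position blocks before windowing."""
    L = len(pred.sequence)
    blocks = np.zeros((L, 23))
    if cfg.feature_set == "basic":
        for i, aa in enumerate(pred.sequence):
            k = AA_INDEX.get(aa)
            if k is not None:  # 'X' leaves an all-zero amino-acid block
                blocks[i, k] = 1.0
    else:
        if pred.pssm is None:
            raise InputError(
                f"feature set {cfg.feature_set!r} needs a PSSM profile"
            )
        blocks[:, :20] = _logistic(pred.pssm)
    for i in range(L):
        blocks[i, 20] = 1.0 if model_feats.ss3[i] == pred.ss3_pred[i] else 0.0
        blocks[i, 21] = 1.0 if model_feats.exposure2[i] == pred.exposure2_pred[i] else 0.0
        blocks[i, 22] = contact_agreement_feature(
            i + 1, model_feats.contacts, pred.contact_prob
        )
    return blocks


def encode_residue(
    center: int,
    model_feats: ModelDerivedFeatures,
    pred: PredictedAnnotations,
    cfg: EncodingConfig | None = None,
) -> np.ndarray:
    """Feature vector for one residue (1-based ``center``)."""
    cfg = cfg or EncodingConfig()
    L = len(pred.sequence)
    if not 1 <= center <= L:
        raise InputError(f"center {center} outside 1..{L}")
    blocks = _position_blocks(model_feats, pred, cfg)
    half = cfg.window // 2
    padded = np.vstack(
        [np.zeros((half, 23)), blocks, np.zeros((half, 23))]
    )
    vec = padded[center - 1 : center - 1 + cfg.window].ravel()
    if cfg.feature_set == "profile_sov":
        vec = np.append(vec, sov_score(model_feats.ss3, pred.ss3_pred).sov_total)
    return vec


def encode_model(
    model: ProteinModel,
    pred: PredictedAnnotations,
    cfg: EncodingConfig | None = None,
    native: ProteinModel | None = None,
    model_feats: ModelDerivedFeatures | None = None,
    allow_partial: bool = False,
) -> ExampleSet:
    """One feature row per residue of a model; targets from the native.

    Models that are incomplete with respect to the target sequence are
    rejected (``allow_partial`` overrides, mirroring that partial models
    are normally discarded). ``model_feats`` may be supplied to reuse a
    precomputed derivation.
    """
    cfg = cfg or EncodingConfig()
    report = check_completeness(model, pred.sequence)
    if not report.complete and not allow_partial:
        raise IncompleteModelError(
            f"model {model.model_id} is incomplete w.r.t. the target sequence "
            f"(missing={sorted(report.missing)[:8]}, "
            f"mismatches={sorted(report.mismatches)[:8]}, "
            f"no_CA={sorted(report.missing_ca)[:8]}); partial models are discarded"
        )
    if model_feats is None:
        model_feats = derive_features(
            model,
            min_separation=cfg.contact_min_sep,
            max_distance=cfg.contact_max_dist,
        )
    L = len(model)
    blocks = _position_blocks(model_feats, pred, cfg)
    half = cfg.window // 2
    padded = np.vstack([np.zeros((half, 23)), blocks, np.zeros((half, 23))])
    windows = np.stack(
        [padded[i : i + cfg.window].ravel() for i in range(L)]
    )
    if cfg.feature_set == "profile_sov":
        sov = sov_score(model_feats.ss3, pred.ss3_pred).sov_total
        windows = np.hstack([windows, np.full((L, 1), sov)])

    targets = None
    if native is not None:
        from .evaluation import superimpose  # local import: avoid cycle

        dev = superimpose(model, native).per_residue_deviation
        if cfg.target_cap is not None:
            dev = np.minimum(dev, cfg.target_cap)
        targets = dev

    return ExampleSet(
        features=windows,
        targets=targets,
        residue_ids=[(model.model_id, i + 1) for i in range(L)],
        feature_set=cfg.feature_set,
        window=cfg.window,
    )
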