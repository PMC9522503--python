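"""End-to-end sleep stager: preprocess -> branches -> fusion -> HMM.

:class:`TemporalContextSleepStager` is the headline estimator.  ``fit`` takes
raw 30 s epochs ``(n, 3000)``, stage labels and recording ids; it standardizes
signals, computes filter-bank spectrograms, trains the TCN and/or CNN
one-to-many branches, calibrates the fusion weights from validation
accuracies, and estimates the HMM from training labels and the training-set
confusion of the fused classifier.  ``predict`` runs the same chain per
recording and returns fine-tuned stage labels.

Ablation switches reproduce the model family's variants: CNN only
(``use_tcn=False, fusion_mode='none', use_hmm=False``); + TCN (both branches,
no fusion/HMM); + HMM; + balanced fusion (``fusion_mode='balanced'``);
+ weighted fusion (``fusion_mode='weighted'``); and the full model (weighted
fusion + HMM).

:func:`run_pipeline` drives subject-level cross-validation over a dataset and
pools test confusion matrices across folds.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.utils.validation import check_is_fitted

from .evaluation import (
    ConfusionMatrix,
    FoldPlan,
    MetricReport,
    confusion,
    make_folds,
    metrics,
    pooled_confusion,
)
from .fusion import ContextFusion
from .hmm import HmmFineTuner
from .models import CnnBranchClassifier, TcnBranchClassifier
from .preprocessing import SpectrogramTransformer, standardize_signals
from .simulate import SyntheticRecording, dataset_arrays


class TemporalContextSleepStager(ClassifierMixin, BaseEstimator):
    """Multilevel temporal-context sleep stage classifier.

    Parameters
    ----------
    tcn, cnn
        Branch prototypes (cloned at fit).  None uses branch defaults.
    use_tcn, use_cnn
        Enable the temporal (raw-signal) and spectral (spectrogram) branches;
        at least one must be on.
    fusion_mode
        'weighted' (squared accuracy-ratio weights), 'balanced' (equal
        weights) or 'none' (per-epoch classification only).
    use_hmm
        Apply windowed Viterbi fine-tuning to the fused labels.
    emission_source
        Which split's confusion matrix feeds the HMM emission estimate:
        'train' (default) or 'validation'.
    """

    def __init__(
        self,
        tcn: TcnBranchClassifier | None = None,
        cnn: CnnBranchClassifier | None = None,
        use_tcn: bool = True,
        use_cnn: bool = True,
        fusion_mode: str = "weighted",
        branch_merge: str = "mean",
        use_hmm: bool = True,
        hmm_window_length: int = 17,
        hmm_smoothing: float = 1e-6,
        emission_source: str = "train",
        standardization_scope: str = "per_recording",
        n_filters: int = 20,
        freq_range: tuple[float, float] = (0.5, 49.0),
        validation_fraction: float = 0.2,
        seed: int = 0,
    ):
        self.tcn = tcn
        self.cnn = cnn
        self.use_tcn = use_tcn
        self.use_cnn = use_cnn
        self.fusion_mode = fusion_mode
        self.branch_merge = branch_merge
        self.use_hmm = use_hmm
        self.hmm_window_length = hmm_window_length
        self.hmm_smoothing = hmm_smoothing
        self.emission_source = emission_source
        self.standardization_scope = standardization_scope
        self.n_filters = n_filters
        self.freq_range = freq_range
        self.validation_fraction = validation_fraction
        self.seed = seed

    # -- representation helpers ------------------------------------------

    def _standardize(self, X, groups):
        return standardize_signals(
            np.asarray(X, dtype=float), scope=self.standardization_scope, groups=groups
        )

    def _representations(self, X, groups):
        std = self._standardize(X, groups)
        specs = self.spectrogram_.transform(std)
        return std, specs

    def _branch_context(self, std, specs):
        probs = []
        if self.use_tcn:
            probs.append(self.tcn_.predict_context_proba(std))
        if self.use_cnn:
            probs.append(self.cnn_.predict_context_proba(specs))
        return probs

    def _fused_labels_by_recording(self, X, groups):
        groups = np.asarray(groups)
        std, specs = self._representations(X, groups)
        out_labels = np.empty(std.shape[0], dtype=np.int64)
        for g in _unique_stable(groups):
            mask = groups == g
            probs = self._branch_context(std[mask], specs[mask])
            labels, _ = self.fusion_.transform(probs)
            out_labels[mask] = labels
        return out_labels

    # -- estimator API ---------------------------------------------------

    def fit(
        self,
        X,
        y,
        groups=None,
        X_val=None,
        y_val=None,
        groups_val=None,
    ):
        if not self.use_tcn and not self.use_cnn:
            raise ValueError(
                "inconsistent ablation flags: HMM/fusion without any branch "
                "classifier (enable use_tcn and/or use_cnn)"
            )
        if self.use_hmm and self.fusion_mode not in ("none", "balanced", "weighted"):
            raise ValueError(f"unknown fusion mode {self.fusion_mode!r}")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=np.int64)
        groups = np.zeros(y.size, dtype=int) if groups is None else np.asarray(groups)
        if X_val is None:
            X, y, groups, X_val, y_val, groups_val = _holdout_recordings(
                X, y, groups, self.validation_fraction
            )
        else:
            X_val = np.asarray(X_val, dtype=float)
            y_val = np.asarray(y_val, dtype=np.int64)
            groups_val = (
                np.zeros(y_val.size, dtype=int) if groups_val is None else np.asarray(groups_val)
            )

        self.spectrogram_ = SpectrogramTransformer(
            n_filters=self.n_filters, freq_range=self.freq_range
        ).fit()
        std, specs = self._representations(X, groups)
        std_val, specs_val = self._representations(X_val, groups_val)

        accuracies = []
        if self.use_tcn:
            proto = self.tcn if self.tcn is not None else TcnBranchClassifier()
            self.tcn_ = clone(proto)
            self.tcn_.set_params(seed=self.seed)
            self.tcn_.fit(std, y, groups=groups, X_val=std_val, y_val=y_val, groups_val=groups_val)
            accuracies.append(
                (self.tcn_.pre_acc_prev_, self.tcn_.acc_current_, self.tcn_.pre_acc_next_)
            )
        if self.use_cnn:
            proto = self.cnn if self.cnn is not None else CnnBranchClassifier()
            self.cnn_ = clone(proto)
            self.cnn_.set_params(seed=self.seed + 1)
            self.cnn_.fit(
                specs, y, groups=groups, X_val=specs_val, y_val=y_val, groups_val=groups_val
            )
            accuracies.append(
                (self.cnn_.pre_acc_prev_, self.cnn_.acc_current_, self.cnn_.pre_acc_next_)
            )

        self.fusion_ = ContextFusion(mode=self.fusion_mode, merge=self.branch_merge)
        self.fusion_.fit(accuracies, y_train=y)

        if self.use_hmm:
            if self.emission_source == "train":
                em_X, em_y, em_groups = X, y, groups
            elif self.emission_source == "validation":
                em_X, em_y, em_groups = X_val, y_val, groups_val
            else:
                raise ValueError(f"unknown emission_source {self.emission_source!r}")
            fused_em = self._fused_labels_by_recording(em_X, em_groups)
            train_seqs = [y[groups == g] for g in _unique_stable(groups)]
            self.hmm_ = HmmFineTuner(
                window_length=self.hmm_window_length, smoothing=self.hmm_smoothing
            ).fit(train_seqs, confusion(em_y, fused_em).counts)
        self.classes_ = np.arange(5)
        return self

    def predict(self, X, groups=None) -> np.ndarray:
        check_is_fitted(self, "fusion_")
        X = np.asarray(X, dtype=float)
        groups = np.zeros(X.shape[0], dtype=int) if groups is None else np.asarray(groups)
        fused = self._fused_labels_by_recording(X, groups)
        if not self.use_hmm:
            return fused
        out = np.empty_like(fused)
        for g in _unique_stable(groups):
            mask = groups == g
            out[mask] = self.hmm_.predict(fused[mask])
        return out

    def predict_scores(self, X, groups=None) -> np.ndarray:
        """Merged fused score vectors (n, 5) before HMM fine-tuning."""
        check_is_fitted(self, "fusion_")
        X = np.asarray(X, dtype=float)
        groups = np.zeros(X.shape[0], dtype=int) if groups is None else np.asarray(groups)
        std, specs = self._representations(X, groups)
        scores = np.empty((X.shape[0], 5))
        for g in _unique_stable(groups):
            mask = groups == g
            _, s = self.fusion_.transform(self._branch_context(std[mask], specs[mask]))
            scores[mask] = s
        return scores


def _unique_stable(values: np.ndarray):
    return list(dict.fromkeys(values.tolist()))


def _holdout_recordings(X, y, groups, fraction):
    uniq = _unique_stable(groups)
    n_val = max(1, int(round(len(uniq) * fraction))) if len(uniq) > 1 else 0
    if n_val == 0:
        cut = max(1, int(round(y.size * (1 - fraction))))
        return X[:cut], y[:cut], groups[:cut], X[cut:], y[cut:], groups[cut:]
    val = set(uniq[-n_val:])
    mask = np.asarray([g in val for g in groups])
    return X[~mask], y[~mask], groups[~mask], X[mask], y[mask], groups[mask]


# ---------------------------------------------------------------------------
# cross-validation driver


@dataclasses.dataclass
class PipelineConfig:
    """Bundle of pipeline settings for cross-validated runs.

    Branch prototypes default to the published-scale hyperparameters; pass
    smaller branches for desk-scale runs.
    """

    tcn: TcnBranchClassifier | None = None
    cnn: CnnBranchClassifier | None = None
    use_tcn: bool = True
    use_cnn: bool = True
    fusion_mode: str = "weighted"
    branch_merge: str = "mean"
    use_hmm: bool = True
    hmm_window_length: int = 17
    hmm_smoothing: float = 1e-6
    emission_source: str = "train"
    standardization_scope: str = "per_recording"
    n_filters: int = 20
    freq_range: tuple[float, float] = (0.5, 49.0)
    seed: int = 0

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        """Build from a declarative mapping (e.g. a parsed YAML file).

        Keys ``tcn`` and ``cnn`` may hold branch hyperparameter mappings.
        """
        payload = dict(payload)
        tcn = payload.pop("tcn", None)
        cnn = payload.pop("cnn", None)
        if isinstance(tcn, dict):
            tcn = TcnBranchClassifier(**tcn)
        if isinstance(cnn, dict):
            cnn = CnnBranchClassifier(**cnn)
        if "freq_range" in payload:
            payload["freq_range"] = tuple(payload["freq_range"])
        return cls(tcn=tcn, cnn=cnn, **payload)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def build(self) -> TemporalContextSleepStager:
        return TemporalContextSleepStager(
            tcn=self.tcn,
            cnn=self.cnn,
            use_tcn=self.use_tcn,
            use_cnn=self.use_cnn,
            fusion_mode=self.fusion_mode,
            branch_merge=self.branch_merge,
            use_hmm=self.use_hmm,
            hmm_window_length=self.hmm_window_length,
            hmm_smoothing=self.hmm_smoothing,
            emission_source=self.emission_source,
            standardization_scope=self.standardization_scope,
            n_filters=self.n_filters,
            freq_range=self.freq_range,
            seed=self.seed,
        )


VARIANTS: dict[str, dict] = {
    # ablation family: spectral branch alone up to the full model
    "variant1": {"use_tcn": False, "fusion_mode": "none", "use_hmm": False},
    "variant2": {"use_tcn": True, "fusion_mode": "none", "use_hmm": False},
    "variant3": {"use_tcn": True, "fusion_mode": "none", "use_hmm": True},
    "variant4": {"use_tcn": True, "fusion_mode": "balanced", "use_hmm": False},
    "variant5": {"use_tcn": True, "fusion_mode": "weighted", "use_hmm": False},
    "full": {"use_tcn": True, "fusion_mode": "weighted", "use_hmm": True},
}


@dataclasses.dataclass
class FoldResult:
    fold: int
    report: MetricReport
    confusion: ConfusionMatrix
    hypnograms: dict[str, dict[str, np.ndarray]]  # recording -> {'true','predicted'}


@dataclasses.dataclass
class PipelineResult:
    fold_results: list[FoldResult]
    pooled_report: MetricReport
    pooled_confusion: ConfusionMatrix


def run_pipeline(
    recordings: Sequence[SyntheticRecording],
    config: PipelineConfig | None = None,
    fold_plan: FoldPlan | None = None,
    folds: Sequence[int] | None = None,
    variant: str | None = None,
) -> PipelineResult:
    """Cross-validated end-to-end run over a dataset of labeled recordings.

    ``variant`` (optional) overrides the ablation switches with one of the
    named configurations in :data:`VARIANTS`.  ``folds`` restricts execution
    to a subset of the plan's folds; test confusion matrices of the executed
    folds are pooled.
    """
    config = config or PipelineConfig()
    if variant is not None:
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; choose from {sorted(VARIANTS)}")
        config = dataclasses.replace(config, **VARIANTS[variant])
    rec_by_id = {r.recording_id: r for r in recordings}
    if fold_plan is None:
        subjects = {r.recording_id: r.subject_id for r in recordings}
        n_subjects = len(set(subjects.values()))
        n_val = min(4, max(1, n_subjects - 2))
        fold_plan = make_folds(subjects, k=n_subjects, n_validation_subjects=n_val, seed=config.seed)
    fold_ids = list(folds) if folds is not None else list(range(len(fold_plan.folds)))

    fold_results = []
    for i in fold_ids:
        split = fold_plan.recording_split(i)
        for name in ("train", "validation", "test"):
            if not split[name]:
                raise ValueError(f"fold {i} has an empty {name} split")
        tr = [rec_by_id[r] for r in split["train"]]
        va = [rec_by_id[r] for r in split["validation"]]
        te = [rec_by_id[r] for r in split["test"]]
        X, y, groups, _ = dataset_arrays(tr)
        Xv, yv, gv, _ = dataset_arrays(va)
        Xt, yt, gt, _ = dataset_arrays(te)
        stager = config.build()
        stager.fit(X, y, groups=groups, X_val=Xv, y_val=yv, groups_val=gv)
        pred = stager.predict(Xt, groups=gt)
        cm = confusion(yt, pred)
        hyps = {
            r.recording_id: {
                "true": yt[gt == r.recording_id],
                "predicted": pred[gt == r.recording_id],
            }
            for r in te
        }
        fold_results.append(FoldResult(fold=i, report=metrics(cm), confusion=cm, hypnograms=hyps))

    pooled_cm = pooled_confusion([f.confusion for f in fold_results])
    return PipelineResult(
        fold_results=fold_results,
        pooled_report=metrics(pooled_cm),
        pooled_confusion=pooled_cm,
    )
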