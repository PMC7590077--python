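"""Decision flowchart, cross-validation orchestration, and evaluation.

The final positive/negative call for each scan follows a strict
hierarchy.  If the nearest-neighbour stage returned a result, its
averaged concentration alone decides: above the weight-percent threshold
(default 20 wt%) is positive, otherwise negative, and the ensemble stage
is ignored.  Only when the nearest-neighbour stage abstained does the
ensemble stage decide: positive requires an assigned salt form (HCl or
base) *and* a predicted concentration above the threshold; everything
else is negative.  At the sample level the replicate verdicts are
majority-voted, with ties resolved to negative — false positives being
the costliest error of a presumptive drug test.

Evaluation reproduces the study protocol: leave-one-sample-out
cross-validation for the nearest-neighbour stage, grouped 10-fold
cross-validation for the ensemble stage, confusion rates against
laboratory ground truth, predicted-vs-known concentration fits, and the
false-positive / true-positive trade-off as the threshold sweeps 0-100.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ensemble_models import (
    AnnConfig,
    TreebagConfig,
    fit_concentration_regressor,
    fit_form_classifier,
    grouped_cv_folds,
    predict_submodel_b,
)
from .knn_engine import (
    KnnConfig,
    KnnResult,
    OutlierConfig,
    flag_outliers,
    knn_predict,
    query_neighbors,
)
from .preprocessing import PreprocessConfig, preprocess_library
from .spectral_core import CocaineForm, LabeledLibrary, SampleMeta

__all__ = [
    "DecisionConfig",
    "SpectrumVerdict",
    "SampleVerdict",
    "ScanPrediction",
    "CrossValidationResult",
    "EvaluationReport",
    "ThresholdCurve",
    "decide_spectrum",
    "decide_sample",
    "loso_cross_validate",
    "confusion_report",
    "concentration_fit_metrics",
    "threshold_curve",
]

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class DecisionConfig:
    """Weight-percent cocaine threshold of the decision flowchart."""

    conc_threshold_wt_pct: float = 20.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.conc_threshold_wt_pct <= 100.0:
            raise ValueError("threshold must be within [0, 100] wt%")


@dataclass
class SpectrumVerdict:
    """Final per-scan decision with provenance."""

    scan_id: str
    sample_id: str
    result: str  # "positive" | "negative"
    decided_by: str  # "knn" | "ann_treebag"
    predicted_conc: float | None
    predicted_identity: str | None
    mean_neighbor_distance: float | None = None


@dataclass
class SampleVerdict:
    """Majority-voted per-sample decision."""

    sample_id: str
    result: str
    n_positive: int
    n_negative: int
    predicted_identity: str | None


@dataclass
class ScanPrediction:
    """Raw submodel outputs for one scan, before thresholding.

    Kept threshold-free so the decision rule can be re-applied over a
    grid of thresholds without re-running any model.
    """

    scan_id: str
    sample_id: str
    knn_status: str
    knn_conc: float | None
    knn_identity: str | None
    knn_mean_distance: float | None
    b_form: str
    b_conc: float | None


@dataclass
class CrossValidationResult:
    scan_predictions: list[ScanPrediction]
    spectrum_verdicts: list[SpectrumVerdict]
    sample_verdicts: list[SampleVerdict]
    outlier_mask: np.ndarray
    preprocess_tag: str

    def verdict_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    scan_id=v.scan_id,
                    sample_id=v.sample_id,
                    result=v.result,
                    decided_by=v.decided_by,
                    predicted_conc=v.predicted_conc,
                    predicted_identity=v.predicted_identity,
                )
                for v in self.spectrum_verdicts
            ]
        )

    def sample_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    sample_id=v.sample_id,
                    result=v.result,
                    n_positive=v.n_positive,
                    n_negative=v.n_negative,
                    predicted_identity=v.predicted_identity,
                )
                for v in self.sample_verdicts
            ]
        )


@dataclass
class EvaluationReport:
    """Confusion counts and rates at one level (scan or sample)."""

    level: str
    tp: int
    fn: int
    tn: int
    fp: int
    n_excluded: int = 0
    r_squared: float | None = None
    rmse: float | None = None

    @property
    def tp_rate(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def fn_rate(self) -> float:
        return 100.0 * self.fn / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def tn_rate(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp) if self.tn + self.fp else 0.0

    @property
    def fp_rate(self) -> float:
        return 100.0 * self.fp / (self.tn + self.fp) if self.tn + self.fp else 0.0


def decide_spectrum(
    knn: KnnResult,
    submodel_b: tuple[str, float | None],
    config: DecisionConfig | None = None,
    scan_id: str = "",
    sample_id: str = "",
) -> SpectrumVerdict:
    """Apply the decision hierarchy to one scan.

    The nearest-neighbour result, when present, is final; concentration
    strictly above the threshold is positive (equal is negative).  On
    abstention the ensemble result decides, requiring both an assigned
    form and a concentration strictly above the threshold.
    """
    if config is None:
        config = DecisionConfig()
    t = config.conc_threshold_wt_pct
    form, b_conc = submodel_b
    if knn.status == "ok":
        positive = knn.predicted_conc_wt_pct is not None and (
            knn.predicted_conc_wt_pct > t
        )
        return SpectrumVerdict(
            scan_id=scan_id,
            sample_id=sample_id,
            result=POSITIVE if positive else NEGATIVE,
            decided_by="knn",
            predicted_conc=knn.predicted_conc_wt_pct,
            predicted_identity=knn.predicted_identity,
            mean_neighbor_distance=knn.mean_neighbor_distance,
        )
    positive = form in ("hcl", "base") and b_conc is not None and b_conc > t
    return SpectrumVerdict(
        scan_id=scan_id,
        sample_id=sample_id,
        result=POSITIVE if positive else NEGATIVE,
        decided_by="ann_treebag",
        predicted_conc=b_conc,
        predicted_identity=None,
        mean_neighbor_distance=None,
    )


def decide_sample(verdicts: Sequence[SpectrumVerdict]) -> SampleVerdict:
    """Majority-vote replicate verdicts; ties resolve to negative.

    The sample identity is the modal nearest-neighbour identity over the
    scans decided by the kNN stage (ties towards the smallest mean
    neighbour distance); None when no scan carried an identity.
    """
    if not verdicts:
        raise ValueError("decide_sample needs at least one verdict")
    sample_ids = {v.sample_id for v in verdicts}
    if len(sample_ids) != 1:
        raise ValueError(f"verdicts span multiple samples: {sorted(sample_ids)}")
    n_pos = sum(v.result == POSITIVE for v in verdicts)
    n_neg = len(verdicts) - n_pos
    ided = [
        v
        for v in verdicts
        if v.decided_by == "knn" and v.predicted_identity is not None
    ]
    identity: str | None = None
    if ided:
        counts = Counter(v.predicted_identity for v in ided)
        top = max(counts.values())
        tied = [i for i, c in counts.items() if c == top]
        if len(tied) == 1:
            identity = tied[0]
        else:
            mean_d = {
                i: np.mean(
                    [
                        v.mean_neighbor_distance
                        for v in ided
                        if v.predicted_identity == i
                        and v.mean_neighbor_distance is not None
                    ]
                    or [np.inf]
                )
                for i in tied
            }
            identity = min(tied, key=lambda i: (mean_d[i], i))
    return SampleVerdict(
        sample_id=verdicts[0].sample_id,
        result=POSITIVE if n_pos > n_neg else NEGATIVE,
        n_positive=n_pos,
        n_negative=n_neg,
        predicted_identity=identity,
    )


def loso_cross_validate(
    library: LabeledLibrary,
    preprocess: PreprocessConfig | None = None,
    outlier: OutlierConfig | None = None,
    knn: KnnConfig | None = None,
    ann: AnnConfig | None = None,
    treebag: TreebagConfig | None = None,
    decision: DecisionConfig | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> CrossValidationResult:
    """Run the full multistage pipeline under cross-validation.

    The raw library is preprocessed, replicate outliers are flagged (and
    excluded from every training set and from the verdict tally), then:

    * the kNN stage answers each scan with all scans of the scan's own
      sample excluded (leave-one-sample-out);
    * the ensemble stage answers each scan from the grouped-fold models
      whose held-out fold contains the scan's sample (folds are whole
      samples; at most ``n_folds``, fewer when the library is small).

    Every non-outlier scan receives a :class:`SpectrumVerdict`, and the
    replicate verdicts are majority-voted into per-sample verdicts.
    """
    if preprocess is None:
        preprocess = PreprocessConfig()
    if outlier is None:
        outlier = OutlierConfig()
    if knn is None:
        knn = KnnConfig()
    if ann is None:
        ann = AnnConfig(seed=seed)
    if treebag is None:
        treebag = TreebagConfig(seed=seed)
    if decision is None:
        decision = DecisionConfig()
    if len(set(library.sample_ids)) < 2:
        raise ValueError("cross-validation needs at least 2 samples")

    lib = preprocess_library(library, preprocess)
    out_mask = flag_outliers(lib, outlier)
    clean = ~out_mask
    sample_ids = lib.sample_ids

    # --- submodel A: leave-one-sample-out kNN over non-outlier rows
    knn_results: dict[int, KnnResult] = {}
    for i in np.nonzero(clean)[0]:
        neigh = query_neighbors(
            lib.matrix[i],
            lib,
            knn,
            excluded_sample_ids={sample_ids[i]},
            candidate_mask=clean,
        )
        knn_results[int(i)] = knn_predict(neigh, lib)

    # --- submodel B: grouped-fold ANN gate + per-form treebags
    unique_samples = list(dict.fromkeys(sample_ids))
    folds = grouped_cv_folds(unique_samples, min(n_folds, len(unique_samples)), seed)
    fold_of_row = np.array([folds[s] for s in sample_ids])
    b_out: dict[int, tuple[str, float | None]] = {}
    forms = np.array(
        [lib.meta_for_row(i).cocaine_form.value for i in range(lib.n_scans)]
    )
    for f in sorted(set(folds.values())):
        test_rows = np.nonzero(clean & (fold_of_row == f))[0]
        if test_rows.size == 0:
            continue
        train_mask = clean & (fold_of_row != f)
        train_forms = set(forms[train_mask]) - {CocaineForm.NONE.value}
        if len(train_forms) < 2:
            # too few cocaine classes in this training split to train the
            # gate: the ensemble stage cannot assign a form
            preds = [("unassigned", None)] * test_rows.size
        else:
            classifier = fit_form_classifier(lib, ann, row_mask=train_mask)
            regressors = {
                "hcl": fit_concentration_regressor(
                    lib, CocaineForm.HCL, treebag, row_mask=train_mask
                ),
                "base": fit_concentration_regressor(
                    lib, CocaineForm.BASE, treebag, row_mask=train_mask
                ),
            }
            preds = predict_submodel_b(
                lib.matrix[test_rows], classifier, regressors, lib.preprocess_tag
            )
        for row, pred in zip(test_rows, preds):
            b_out[int(row)] = pred

    # --- decisions
    scan_ids = lib.scan_ids
    predictions: list[ScanPrediction] = []
    verdicts: list[SpectrumVerdict] = []
    for i in sorted(knn_results):
        res = knn_results[i]
        form, conc = b_out[i]
        predictions.append(
            ScanPrediction(
                scan_id=scan_ids[i],
                sample_id=sample_ids[i],
                knn_status=res.status,
                knn_conc=res.predicted_conc_wt_pct,
                knn_identity=res.predicted_identity,
                knn_mean_distance=res.mean_neighbor_distance,
                b_form=form,
                b_conc=conc,
            )
        )
        verdicts.append(
            decide_spectrum(
                res,
                (form, conc),
                decision,
                scan_id=scan_ids[i],
                sample_id=sample_ids[i],
            )
        )

    by_sample: dict[str, list[SpectrumVerdict]] = {}
    for v in verdicts:
        by_sample.setdefault(v.sample_id, []).append(v)
    sample_verdicts = [
        decide_sample(vs) for vs in by_sample.values()
    ]
    return CrossValidationResult(
        scan_predictions=predictions,
        spectrum_verdicts=verdicts,
        sample_verdicts=sample_verdicts,
        outlier_mask=out_mask,
        preprocess_tag=lib.preprocess_tag,
    )


def _truth_label(
    meta: SampleMeta, threshold: float
) -> str | None:
    """Ground truth at the evaluation convention.

    Positive: cocaine present above the threshold.  Negative: no cocaine.
    Cocaine-containing samples at or below the threshold are deliberate
    false negatives of the screening rule and are excluded (None).
    """
    if meta.cocaine_form is CocaineForm.NONE:
        return NEGATIVE
    if meta.cocaine_wt_pct > threshold:
        return POSITIVE
    return None


def confusion_report(
    verdicts: Sequence[SpectrumVerdict] | Sequence[SampleVerdict],
    sample_meta: Mapping[str, SampleMeta],
    decision: DecisionConfig | None = None,
    level: str = "scan",
    include_subthreshold: bool = False,
) -> EvaluationReport:
    """Tally verdicts against laboratory ground truth.

    A sample is truly positive when it contains cocaine above the decision
    threshold; truly negative when it contains none.  Cocaine samples at
    or below the threshold are excluded by default (their negatives are
    deliberate); pass ``include_subthreshold=True`` to count them as
    positives instead.
    """
    if decision is None:
        decision = DecisionConfig()
    t = decision.conc_threshold_wt_pct
    tp = fn = tn = fp = excluded = 0
    for v in verdicts:
        if v.sample_id not in sample_meta:
            raise KeyError(f"no metadata for sample {v.sample_id!r}")
        meta = sample_meta[v.sample_id]
        truth = _truth_label(meta, t)
        if truth is None:
            if include_subthreshold:
                truth = POSITIVE
            else:
                excluded += 1
                continue
        if truth == POSITIVE:
            if v.result == POSITIVE:
                tp += 1
            else:
                fn += 1
        else:
            if v.result == NEGATIVE:
                tn += 1
            else:
                fp += 1
    return EvaluationReport(
        level=level, tp=tp, fn=fn, tn=tn, fp=fp, n_excluded=excluded
    )


def concentration_fit_metrics(
    predicted: Sequence[float | None], known: Sequence[float]
) -> tuple[float, float]:
    """R^2 (squared Pearson correlation) and RMSE of predicted vs known.

    Pairs with a missing prediction (abstentions) are dropped.  Raises on
    zero variance in either remaining list, where R^2 is undefined.
    """
    if len(predicted) != len(known):
        raise ValueError("predicted and known must have equal length")
    pairs = [(p, k) for p, k in zip(predicted, known) if p is not None]
    if len(pairs) < 2:
        raise ValueError("need at least 2 non-missing pairs")
    p = np.array([x for x, _ in pairs], dtype=float)
    k = np.array([x for _, x in pairs], dtype=float)
    if p.std() == 0.0 or k.std() == 0.0:
        raise ValueError("zero variance: R^2 undefined")
    r = np.corrcoef(p, k)[0, 1]
    rmse = float(np.sqrt(np.mean((p - k) ** 2)))
    return float(r**2), rmse


@dataclass
class ThresholdCurve:
    """FP/TP rates of the decision rule over a threshold sweep.

    Ground-truth labels stay fixed at the evaluation convention of the
    base decision config; only the decision rule is re-applied.
    """

    thresholds: np.ndarray
    fp_rate: np.ndarray
    tp_rate: np.ndarray
    accuracy: np.ndarray
    zero_fp_threshold: float | None
    max_accuracy_threshold: float
    min_fn_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold_wt_pct": self.thresholds,
                "fp_rate": self.fp_rate,
                "tp_rate": self.tp_rate,
                "accuracy": self.accuracy,
            }
        )


def threshold_curve(
    predictions: Sequence[ScanPrediction],
    sample_meta: Mapping[str, SampleMeta],
    thresholds: Sequence[float],
    decision: DecisionConfig | None = None,
) -> ThresholdCurve:
    """Re-apply the decision flowchart over a grid of wt% thresholds.

    Models are never re-run: each scan's stored submodel outputs are
    pushed through the decision rule at every threshold and tallied
    against fixed ground truth.  Reports the smallest zero-FP threshold,
    the highest-accuracy threshold, and the largest threshold attaining
    the minimal FN rate (the three operating points of a screening
    trade-off curve).
    """
    thresholds = np.asarray(sorted(thresholds), dtype=float)
    if thresholds.size == 0:
        raise ValueError("threshold grid is empty")
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    if decision is None:
        decision = DecisionConfig()

    truth = []
    for pr in predictions:
        if pr.sample_id not in sample_meta:
            raise KeyError(f"no metadata for sample {pr.sample_id!r}")
        truth.append(
            _truth_label(sample_meta[pr.sample_id], decision.conc_threshold_wt_pct)
        )
    kept = [i for i, tr in enumerate(truth) if tr is not None]
    if not kept:
        raise ValueError("no scans left after excluding sub-threshold samples")

    # effective concentration the flowchart compares against the threshold
    eff = np.full(len(predictions), -np.inf)
    for i, pr in enumerate(predictions):
        if pr.knn_status == "ok":
            eff[i] = pr.knn_conc if pr.knn_conc is not None else -np.inf
        elif pr.b_form in ("hcl", "base") and pr.b_conc is not None:
            eff[i] = pr.b_conc
    eff = eff[kept]
    is_pos = np.array([truth[i] == POSITIVE for i in kept])
    n_pos = int(is_pos.sum())
    n_neg = int((~is_pos).sum())

    fp_rate = np.empty_like(thresholds)
    tp_rate = np.empty_like(thresholds)
    accuracy = np.empty_like(thresholds)
    for j, t in enumerate(thresholds):
        called_pos = eff > t
        tp = int((called_pos & is_pos).sum())
        fp = int((called_pos & ~is_pos).sum())
        tp_rate[j] = 100.0 * tp / n_pos if n_pos else 0.0
        fp_rate[j] = 100.0 * fp / n_neg if n_neg else 0.0
        accuracy[j] = 100.0 * (tp + (n_neg - fp)) / (n_pos + n_neg)

    zero_idx = np.nonzero(fp_rate == 0.0)[0]
    zero_fp = float(thresholds[zero_idx[0]]) if zero_idx.size else None
    best_acc = float(thresholds[int(np.argmax(accuracy))])
    fn_rate = 100.0 - tp_rate
    min_fn = fn_rate.min()
    min_fn_threshold = float(thresholds[np.nonzero(fn_rate == min_fn)[0][-1]])
    return ThresholdCurve(
        thresholds=thresholds,
        fp_rate=fp_rate,
        tp_rate=tp_rate,
        accuracy=accuracy,
        zero_fp_threshold=zero_fp,
        max_accuracy_threshold=best_acc,
        min_fn_threshold=min_fn_threshold,
    )
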