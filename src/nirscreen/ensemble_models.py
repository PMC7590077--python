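"""Salt-form ANN gate and per-form bagged-tree regressors (submodel B).

When the nearest-neighbour stage abstains, a second, always-answering
model takes over.  It has two parts:

* a **form classifier**: PCA compression of the preprocessed spectra to
  the smallest number of components holding 99 % of the variance,
  followed by a small feed-forward network scoring the probability that a
  scan is cocaine *base* (vs cocaine *HCl*).  Only near-certain scores
  are accepted — probability <= 0.05 assigns HCl, >= 0.95 assigns base,
  anything in between leaves the scan *unassigned*.  The classifier is
  trained on cocaine scans only; foreign material is expected to score
  mid-range and be gated out.
* two **concentration regressors**, one per form: ensembles of regression
  trees, each tree fitted on a bootstrap resample of that form's training
  scans (bagging); the prediction is the ensemble mean, clipped to
  [0, 100] wt%.

Cross-validation for these models is *grouped*: all replicate scans of a
physical sample share one fold, so replicate similarity can never leak
between training and test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeRegressor

from .spectral_core import CocaineForm, LabeledLibrary

__all__ = [
    "AnnConfig",
    "TreebagConfig",
    "FormClassifier",
    "ConcentrationRegressor",
    "grouped_cv_folds",
    "fit_form_classifier",
    "assign_form",
    "fit_concentration_regressor",
    "predict_submodel_b",
]


@dataclass(frozen=True)
class AnnConfig:
    """PCA-prescaled network-committee configuration for the salt-form gate.

    ``n_networks`` independently initialised networks are trained and
    their probabilities averaged.  A single network's output on material
    far from the training classes is an artefact of its random
    initialisation (it can saturate to either side); committee members
    disagree on such input, so the averaged probability falls mid-range
    and is gated out, while unanimous members keep in-distribution scans
    beyond the gates.
    """

    variance_retained: float = 0.99
    prob_low: float = 0.05
    prob_high: float = 0.95
    hidden_units: int = 8
    n_networks: int = 9
    max_epochs: int = 500
    alpha: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.variance_retained <= 1.0:
            raise ValueError("variance_retained must be in (0, 1]")
        if not 0.0 < self.prob_low < self.prob_high < 1.0:
            raise ValueError("need 0 < prob_low < prob_high < 1")
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.n_networks < 1:
            raise ValueError("n_networks must be >= 1")


@dataclass(frozen=True)
class TreebagConfig:
    """Bagged regression-tree hyperparameters."""

    n_trees: int = 25
    min_samples_leaf: int = 5
    max_depth: int | None = None
    bootstrap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


def grouped_cv_folds(
    sample_ids: Sequence[str], n_folds: int = 10, seed: int = 0
) -> dict[str, int]:
    """Randomly partition samples into near-equal folds (1..n_folds).

    All scans of one sample inherit that sample's fold, so a fold holds
    out whole samples with all their replicates.  Deterministic for a
    given seed.
    """
    unique = list(dict.fromkeys(sample_ids))
    if n_folds > len(unique):
        raise ValueError(
            f"n_folds={n_folds} exceeds the {len(unique)} distinct samples"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    assignment: dict[str, int] = {}
    for pos, j in enumerate(order):
        assignment[unique[j]] = (pos % n_folds) + 1
    return assignment


@dataclass
class FormClassifier:
    """Trained PCA + network committee scoring P(base | scan)."""

    pca: PCA
    networks: list[MLPClassifier]
    n_components_used: int
    preprocess_tag: str
    config: AnnConfig

    def predict_proba_base(self, X: np.ndarray) -> np.ndarray:
        """Committee-mean probability of the base class per row of ``X``."""
        scores = self.pca.transform(np.atleast_2d(X))
        member_probs = []
        for net in self.networks:
            proba = net.predict_proba(scores)
            base_col = int(np.nonzero(net.classes_ == 1)[0][0])
            member_probs.append(proba[:, base_col])
        return np.mean(member_probs, axis=0)


def fit_form_classifier(
    library: LabeledLibrary,
    config: AnnConfig | None = None,
    row_mask: np.ndarray | None = None,
) -> FormClassifier:
    """Train the HCl/base gate on the library's cocaine scans.

    Rows whose sample has ``cocaine_form == none`` are ignored; an
    optional ``row_mask`` further restricts training (e.g. to non-outlier,
    in-fold scans).  PCA keeps the smallest component count reaching
    ``variance_retained``; each committee member is a single-hidden-layer
    logistic scorer trained to convergence with a deterministic seeded
    solver (member seeds derive from ``config.seed``).
    """
    if config is None:
        config = AnnConfig()
    forms = np.array(
        [library.meta_for_row(i).cocaine_form.value for i in range(library.n_scans)]
    )
    keep = forms != CocaineForm.NONE.value
    if row_mask is not None:
        keep &= np.asarray(row_mask, dtype=bool)
    X = library.matrix[keep]
    y = (forms[keep] == CocaineForm.BASE.value).astype(int)
    if X.shape[0] == 0 or len(np.unique(y)) < 2:
        raise ValueError(
            "form classifier needs training scans of both cocaine forms"
        )

    max_comp = min(X.shape[0], X.shape[1])
    pca = PCA(n_components=max_comp, svd_solver="full").fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, config.variance_retained) + 1)
    n_comp = min(n_comp, max_comp)
    pca = PCA(n_components=n_comp, svd_solver="full").fit(X)

    scores = pca.transform(X)
    seed_rng = np.random.default_rng(config.seed)
    networks = []
    for _ in range(config.n_networks):
        net = MLPClassifier(
            hidden_layer_sizes=(config.hidden_units,),
            activation="logistic",
            solver="lbfgs",
            alpha=config.alpha,
            max_iter=config.max_epochs,
            random_state=int(seed_rng.integers(0, 2**31 - 1)),
        )
        net.fit(scores, y)
        networks.append(net)
    return FormClassifier(
        pca=pca,
        networks=networks,
        n_components_used=n_comp,
        preprocess_tag=library.preprocess_tag,
        config=config,
    )


def assign_form(probability: float, config: AnnConfig | None = None) -> str:
    """Gate a base-class probability into ``hcl``/``base``/``unassigned``.

    Boundary values are inclusive: exactly ``prob_low`` still assigns HCl
    and exactly ``prob_high`` still assigns base.
    """
    if config is None:
        config = AnnConfig()
    if not 0.0 <= probability <= 1.0:
        raise ValueError("probability must be in [0, 1]")
    if probability <= config.prob_low:
        return "hcl"
    if probability >= config.prob_high:
        return "base"
    return "unassigned"


@dataclass
class ConcentrationRegressor:
    """Bagged regression-tree ensemble for one cocaine form."""

    form: CocaineForm
    trees: list[DecisionTreeRegressor]
    preprocess_tag: str
    config: TreebagConfig

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Ensemble-mean prediction, clipped to [0, 100] wt%."""
        X = np.atleast_2d(X)
        preds = np.mean([t.predict(X) for t in self.trees], axis=0)
        return np.clip(preds, 0.0, 100.0)


def fit_concentration_regressor(
    library: LabeledLibrary,
    form: CocaineForm,
    config: TreebagConfig | None = None,
    row_mask: np.ndarray | None = None,
) -> ConcentrationRegressor:
    """Bag regression trees on one form's scans (features = spectra).

    Each tree sees an independent bootstrap resample (n draws with
    replacement) of the training rows; ``bootstrap=False`` trains every
    tree on the full set, which with ``min_samples_leaf=1`` makes a single
    tree memorise its training points.
    """
    if config is None:
        config = TreebagConfig()
    if form is CocaineForm.NONE:
        raise ValueError("concentration regressors exist only for hcl/base")
    forms = np.array(
        [library.meta_for_row(i).cocaine_form.value for i in range(library.n_scans)]
    )
    keep = forms == form.value
    if row_mask is not None:
        keep &= np.asarray(row_mask, dtype=bool)
    X = library.matrix[keep]
    y = np.array(
        [
            library.meta_for_row(i).cocaine_wt_pct
            for i in np.nonzero(keep)[0]
        ]
    )
    if X.shape[0] == 0:
        raise ValueError(f"no training scans for form {form.value!r}")

    rng = np.random.default_rng(config.seed)
    trees = []
    for _ in range(config.n_trees):
        if config.bootstrap:
            idx = rng.integers(0, X.shape[0], size=X.shape[0])
        else:
            idx = np.arange(X.shape[0])
        tree = DecisionTreeRegressor(
            min_samples_leaf=config.min_samples_leaf,
            max_depth=config.max_depth,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[idx], y[idx])
        trees.append(tree)
    return ConcentrationRegressor(
        form=form,
        trees=trees,
        preprocess_tag=library.preprocess_tag,
        config=config,
    )


def predict_submodel_b(
    X: np.ndarray,
    classifier: FormClassifier,
    regressors: Mapping[str, ConcentrationRegressor],
    preprocess_tag: str | None = None,
) -> list[tuple[str, float | None]]:
    """Gate each scan's form, then predict concentration if assigned.

    Returns one ``(form_assignment, concentration-or-None)`` pair per row.
    Unassigned scans get no concentration.  Refuses inputs whose
    preprocessing fingerprint differs from the models'.
    """
    tags = {classifier.preprocess_tag} | {
        r.preprocess_tag for r in regressors.values()
    }
    if len(tags) != 1:
        raise ValueError(f"models trained under different preprocess tags: {tags}")
    if preprocess_tag is not None and preprocess_tag not in tags:
        raise ValueError(
            f"input preprocess tag {preprocess_tag!r} != model tag {tags.pop()!r}"
        )
    X = np.atleast_2d(np.asarray(X, dtype=float))
    probs = classifier.predict_proba_base(X)
    out: list[tuple[str, float | None]] = []
    cache: dict[str, np.ndarray] = {
        f: reg.predict(X) for f, reg in regressors.items()
    }
    for i, p in enumerate(probs):
        form = assign_form(float(p), classifier.config)
        if form == "unassigned":
            out.append((form, None))
        else:
            out.append((form, float(cache[form][i])))
    return out
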