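"""scikit-learn style estimators wrapping the mixture fit and the rule system.

``MethylationDetector`` is fit on a species' vector of per-CDS O/E CpG
values, exposes the fitted mixture parameters as trailing-underscore
attributes, assigns CDS to the depleted/non-depleted component with
``predict``, and produces the species-level presence call with
``methylation_call``.

``DnmtArchitectureClassifier`` is a stateless rule classifier over domain
architectures; ``fit`` only validates, ``predict`` maps each architecture
(an iterable of domain names) to its DNMT family label.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .calls import MethylationVerdict, call_by_distance, call_provataris
from .cpg import OeCpgProfile, summarize_distribution
from .dnmt import DnmtCall, classify_dnmt
from .mixture import fit_gmm, summarize_bimodality


def _as_1d(X) -> np.ndarray:
    x = np.asarray(X, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x.ravel()
    if x.ndim != 1:
        raise ValueError("expected a 1-D array of O/E values (or a column vector)")
    if not np.all(np.isfinite(x)):
        raise ValueError("O/E values must be finite")
    return x


class MethylationDetector(BaseEstimator):
    """Detect germline DNA methylation from the O/E CpG distribution.

    Fits 1- and 2-component univariate Gaussian mixtures by EM and calls
    methylation present when the distance between the two component means
    reaches ``threshold`` (rule ``"distance"``), or via the three-way
    bimodality classification (rule ``"provataris"``).

    Parameters
    ----------
    threshold : float, default 0.25
        Distance cutoff for the distance rule; the boundary is "present".
    rule : {"distance", "provataris"}, default "distance"
    n_init : int, default 10
        EM restarts per model (one deterministic, the rest seeded random).
    tol, max_iter : EM stopping controls.
    random_state : int, default 0
        Seeds the restarts; the whole fit is deterministic given the data.

    Attributes
    ----------
    fit1_, fit2_ : MixtureFit for the 1- and 2-component models.
    means_, weights_, variances_ : two-component parameters, ascending mean.
    bimodality_ : BimodalitySummary (mean_low, mean_high, d, %low, AICs).
    distance_d_ : float, the calling statistic.
    """

    def __init__(
        self,
        threshold: float = 0.25,
        rule: str = "distance",
        n_init: int = 10,
        tol: float = 1e-6,
        max_iter: int = 500,
        random_state: int = 0,
    ):
        self.threshold = threshold
        self.rule = rule
        self.n_init = n_init
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        """Fit both mixture models to a vector of per-CDS O/E values."""
        if self.rule not in ("distance", "provataris"):
            raise ValueError(f"unknown rule {self.rule!r}")
        x = _as_1d(X)
        self.fit1_ = fit_gmm(
            x, 1, seed=self.random_state, tol=self.tol,
            max_iter=self.max_iter, n_init=self.n_init,
        )
        self.fit2_ = fit_gmm(
            x, 2, seed=self.random_state, tol=self.tol,
            max_iter=self.max_iter, n_init=self.n_init,
        )
        summary = summarize_distribution(OeCpgProfile(species="", values=x))
        self.bimodality_ = summarize_bimodality(self.fit1_, self.fit2_, summary, values=x)
        self.means_ = self.fit2_.means
        self.weights_ = self.fit2_.weights
        self.variances_ = self.fit2_.variances
        self.distance_d_ = self.bimodality_.distance_d
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        """Assign each O/E value to a component: 0 = low mean, 1 = high."""
        check_is_fitted(self, "fit2_")
        x = _as_1d(X)[:, None]
        log_comp = (
            np.log(self.weights_)
            - 0.5 * (np.log(2 * np.pi * self.variances_) + (x - self.means_) ** 2 / self.variances_)
        )
        return np.argmax(log_comp, axis=1)

    def score(self, X, y=None) -> float:
        """Mean per-CDS log-likelihood under the two-component model."""
        check_is_fitted(self, "fit2_")
        from scipy.special import logsumexp

        x = _as_1d(X)[:, None]
        log_comp = (
            np.log(self.weights_)
            - 0.5 * (np.log(2 * np.pi * self.variances_) + (x - self.means_) ** 2 / self.variances_)
        )
        return float(np.mean(logsumexp(log_comp, axis=1)))

    def methylation_call(self, species: str = "") -> MethylationVerdict:
        """The species-level presence/absence verdict under the chosen rule."""
        check_is_fitted(self, "bimodality_")
        if self.rule == "provataris":
            return call_provataris(self.bimodality_, species=species)
        return call_by_distance(self.bimodality_, threshold=self.threshold, species=species)


class DnmtArchitectureClassifier(BaseEstimator):
    """Rule-based DNMT1/2/3 classification of domain architectures.

    Input samples are iterables of Pfam domain names (each must contain the
    catalytic ``DNA_methylase``). The classifier has no free parameters;
    ``fit`` validates the input and returns self so the estimator composes
    with sklearn tooling.
    """

    _classes = np.array(["DNMT1", "DNMT2", "DNMT3", "ambiguous"])

    def fit(self, X: Sequence[Iterable[str]], y=None):
        for arch in X:
            classify_dnmt(arch)
        self.classes_ = self._classes.copy()
        return self

    def predict(self, X: Sequence[Iterable[str]]) -> np.ndarray:
        """Family label per architecture."""
        return np.array([classify_dnmt(arch).dnmt_class for arch in X])

    def predict_calls(self, X: Sequence[Iterable[str]], ids: Sequence[str] | None = None) -> list[DnmtCall]:
        """Full calls (class, completeness, flags) per architecture."""
        if ids is None:
            ids = [f"protein_{i}" for i in range(len(list(X)))]
        return [classify_dnmt(arch, protein_id=pid) for arch, pid in zip(X, ids)]
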