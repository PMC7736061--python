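"""Discriminant analysis of principal components (DAPC).

DAPC first reduces a genotype matrix by PCA (after mean-imputation of missing
calls and per-locus centering, no scaling by default), then runs a linear
discriminant analysis on the retained principal-component scores, maximizing
between-group relative to within-group variance.  New samples are assigned a
posterior membership per group from their Euclidean distance to the group
centroids in discriminant space, assuming an isotropic Gaussian with uniform
priors: posterior_g ∝ exp(-d_g²/2).

The module follows the statsmodels idiom: :class:`DAPC` is the model object
built from data; :meth:`DAPC.fit` returns a :class:`DAPCResults` carrying the
loadings, discriminant axes, centroids and diagnostics, with ``summary()``,
``predict_membership()`` and JSON round-trip serialization.  Helper selection
procedures — stratified cross-validation over the number of retained PCs, the
a-score permutation criterion, and k-means clustering with a BIC curve — hang
off the model object.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.cluster import KMeans

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

_RIDGE = 1e-8
_RANK_TOL = 1e-9


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------

@dataclass
class PreparedMatrix:
    """Samples x loci matrix after mean-imputation and per-locus centering."""

    x: np.ndarray
    locus_means: np.ndarray
    locus_ids: list[str]
    sample_ids: list[str]


def prepare(g: GenotypeMatrix) -> PreparedMatrix:
    """Transpose to samples x loci, impute missing calls with the locus mean
    call, and center each locus by that mean.  No scaling."""
    calls = g.calls.astype(float).T  # samples x loci
    missing = calls == MISSING
    calls[missing] = np.nan
    means = np.nanmean(calls, axis=0)
    zero_call = np.isnan(means)
    if zero_call.any():
        bad = [g.locus_ids[i] for i in np.flatnonzero(zero_call)]
        raise ValueError(f"loci with zero called samples: {bad[:10]}")
    x = np.where(np.isnan(calls), means, calls) - means
    return PreparedMatrix(x, means, list(g.locus_ids), list(g.sample_ids))


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class DAPC:
    """DAPC model over a genotype matrix with per-sample group labels.

    Parameters
    ----------
    genotypes : GenotypeMatrix
        QC-passed loci x samples calls; every locus needs at least one call.
    labels : sequence of str, optional
        Group (strain) label per sample, aligned with ``genotypes.sample_ids``.
        Required for supervised fitting; may be omitted for unsupervised
        clustering via :meth:`kmeans_bic`.
    """

    def __init__(self, genotypes: GenotypeMatrix, labels=None):
        self.genotypes = genotypes
        self.prepared = prepare(genotypes)
        if labels is not None:
            labels = np.asarray([str(l) for l in labels], dtype=object)
            if labels.shape[0] != genotypes.n_samples:
                raise ValueError("labels length does not match sample count")
        self.labels = labels
        # Thin SVD once; PCA for any n_pca is a column slice.
        u, s, vt = np.linalg.svd(self.prepared.x, full_matrices=False)
        self._u, self._s, self._vt = u, s, vt
        if s.size:
            self.rank = max(int(np.sum(s > _RANK_TOL * max(s[0], 1.0))), 1)
        else:
            self.rank = 0

    # -- PCA ---------------------------------------------------------------

    def pc_scores(self, n_pca: int) -> np.ndarray:
        n_pca = self._cap_n_pca(n_pca)
        return self._u[:, :n_pca] * self._s[:n_pca]

    def _cap_n_pca(self, n_pca: int) -> int:
        if n_pca < 1:
            raise ValueError("n_pca must be >= 1")
        if n_pca > self.rank:
            warnings.warn(
                f"n_pca {n_pca} exceeds matrix rank {self.rank}; reduced",
                stacklevel=3,
            )
            return self.rank
        return n_pca

    # -- supervised fit ----------------------------------------------------

    def fit(self, n_pca: int, n_da: int | None = None) -> "DAPCResults":
        """Fit the discriminant analysis on ``n_pca`` retained components.

        ``n_da`` defaults to all available axes and is capped at
        min(n_groups - 1, n_pca).
        """
        if self.labels is None:
            raise ValueError("labels are required for a supervised fit")
        groups = sorted(set(self.labels))
        if len(groups) < 2:
            raise ValueError("at least two groups are required")
        n_pca = self._cap_n_pca(n_pca)
        scores = self.pc_scores(n_pca)
        n, _ = scores.shape
        max_da = min(len(groups) - 1, n_pca)
        n_da = max_da if n_da is None else min(n_da, max_da)

        # Between/within scatter in PC space (covariance scaling by n).
        b = np.zeros((n_pca, n_pca))
        w = np.zeros((n_pca, n_pca))
        group_means = {}
        grand = scores.mean(axis=0)
        for gname in groups:
            sel = self.labels == gname
            xg = scores[sel]
            mu = xg.mean(axis=0)
            group_means[gname] = mu
            dm = (mu - grand)[:, None]
            b += sel.sum() * (dm @ dm.T)
            xc = xg - mu
            w += xc.T @ xc
        b /= n
        w /= n
        min_eig = scipy.linalg.eigvalsh(w, subset_by_index=(0, 0))[0]
        if min_eig < _RIDGE:
            logger.info(
                "within-group scatter near-singular (min eig %.3g); ridge added",
                min_eig,
            )
            w = w + _RIDGE * np.eye(n_pca)
        evals, evecs = scipy.linalg.eigh(b, w)
        order = np.argsort(evals)[::-1][:n_da]
        axes = evecs[:, order]          # n_pca x n_da, W-orthonormal
        eigenvalues = evals[order]

        disc = scores @ axes
        centroids = np.vstack([group_means[gname] @ axes for gname in groups])
        return DAPCResults(
            groups=groups,
            n_pca=n_pca,
            n_da=n_da,
            locus_ids=list(self.prepared.locus_ids),
            locus_means=self.prepared.locus_means.copy(),
            loadings=self._vt[:n_pca].T.copy(),
            disc_axes=axes,
            centroids=centroids,
            eigenvalues=eigenvalues,
            train_sample_ids=list(self.prepared.sample_ids),
            train_labels=list(self.labels),
            train_disc_scores=disc,
        )

    # -- n_pca selection ---------------------------------------------------

    def xval_npca(
        self,
        grid,
        training_fraction: float = 0.75,
        reps: int = 100,
        seed: int = 0,
    ) -> "XvalResult":
        """Stratified cross-validation over candidate numbers of retained PCs.

        Per replicate a stratified ``training_fraction`` of each group trains
        the model and the holdout is predicted; replicate success is the mean
        over groups of the per-group correct fraction.  The per-candidate
        score is RMSE = sqrt(mean over replicates of (1 - success)²); the
        chosen n_pca minimizes RMSE, ties going to the smaller candidate.
        """
        if self.labels is None:
            raise ValueError("labels are required for cross-validation")
        grid = sorted(set(int(c) for c in grid))
        rng = np.random.default_rng(seed)
        groups = sorted(set(self.labels))
        members = {gname: np.flatnonzero(self.labels == gname) for gname in groups}
        for gname, idx in members.items():
            if len(idx) < 2:
                raise ValueError(
                    f"group {gname!r} has {len(idx)} member(s); "
                    "stratified splitting needs at least 2"
                )
        successes = {c: [] for c in grid}
        for _ in range(reps):
            train_idx, test_idx = [], []
            for gname in groups:
                idx = rng.permutation(members[gname])
                n_train = max(1, int(round(training_fraction * len(idx))))
                n_train = min(n_train, len(idx) - 1)
                train_idx.extend(idx[:n_train])
                test_idx.extend(idx[n_train:])
            train_idx = np.asarray(train_idx)
            test_idx = np.asarray(test_idx)
            g_train = self.genotypes.subset(
                samples=[self.genotypes.sample_ids[i] for i in train_idx]
            )
            g_test = self.genotypes.subset(
                samples=[self.genotypes.sample_ids[i] for i in test_idx]
            )
            sub = DAPC(g_train, self.labels[train_idx])
            truth = self.labels[test_idx]
            for cand in grid:
                res = sub.fit(n_pca=cand)
                pred = res.predict_membership(g_test)
                assigned = pred.idxmax(axis=1).to_numpy()
                per_group = [
                    np.mean(assigned[truth == gname] == gname)
                    for gname in groups
                    if np.any(truth == gname)
                ]
                successes[cand].append(float(np.mean(per_group)))
        mean_success = {c: float(np.mean(successes[c])) for c in grid}
        rmse = {
            c: float(np.sqrt(np.mean((1.0 - np.asarray(successes[c])) ** 2)))
            for c in grid
        }
        chosen = min(grid, key=lambda c: (rmse[c], c))
        return XvalResult(grid, mean_success, rmse, chosen)

    def optimize_a_score(self, grid, n_perm: int = 10, seed: int = 0) -> int:
        """Choose n_pca by the a-score: training reassignment success minus
        its expectation under random label permutation (overfit penalty)."""
        if self.labels is None:
            raise ValueError("labels are required for the a-score")
        grid = sorted(set(int(c) for c in grid))
        rng = np.random.default_rng(seed)
        scores = {}
        for cand in grid:
            res = self.fit(n_pca=cand)
            pt = res.reassignment_success()
            prs = []
            for _ in range(n_perm):
                perm_labels = rng.permutation(self.labels)
                perm_res = DAPC(self.genotypes, perm_labels).fit(n_pca=cand)
                prs.append(perm_res.reassignment_success())
            scores[cand] = pt - float(np.mean(prs))
        best = max(grid, key=lambda c: (scores[c], -c))
        return best

    # -- unsupervised clustering -------------------------------------------

    def kmeans_bic(
        self,
        k_range=range(1, 41),
        n_start: int = 1000,
        n_pca: int | None = None,
        seed: int = 0,
    ) -> "BicCurve":
        """k-means over PC scores with a BIC curve across k.

        BIC(k) = n ln(W_k / n) + k ln(n), where W_k is the total
        within-cluster sum of squares at the best of ``n_start`` random
        initializations.  The argmin k is advisory only — flat curves are
        common on admixed data.
        """
        n = self.prepared.x.shape[0]
        n_pca = self.rank if n_pca is None else self._cap_n_pca(n_pca)
        x = self.pc_scores(n_pca)
        ks, bics, assignments = [], [], {}
        for k in k_range:
            if k >= n:
                warnings.warn(f"k={k} >= sample count {n}; skipped", stacklevel=2)
                continue
            km = KMeans(n_clusters=k, n_init=n_start, random_state=seed)
            labels = km.fit_predict(x)
            wk = float(km.inertia_)
            if wk <= 0:
                wk = np.finfo(float).tiny
            ks.append(k)
            bics.append(n * np.log(wk / n) + k * np.log(n))
            assignments[k] = labels
        chosen = ks[int(np.argmin(bics))]
        return BicCurve(ks, bics, assignments, chosen)


@dataclass
class XvalResult:
    grid: list[int]
    mean_success: dict[int, float]
    rmse: dict[int, float]
    chosen_n_pca: int


@dataclass
class BicCurve:
    k_values: list[int]
    bic: list[float]
    assignments: dict[int, np.ndarray]
    chosen_k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_values, "bic": self.bic})


@dataclass
class DAPCResults:
    """Fitted DAPC: loadings, discriminant axes, centroids, diagnostics."""

    groups: list[str]
    n_pca: int
    n_da: int
    locus_ids: list[str]
    locus_means: np.ndarray
    loadings: np.ndarray        # loci x n_pca
    disc_axes: np.ndarray       # n_pca x n_da
    centroids: np.ndarray       # groups x n_da
    eigenvalues: np.ndarray
    train_sample_ids: list[str] = field(default_factory=list)
    train_labels: list[str] = field(default_factory=list)
    train_disc_scores: np.ndarray | None = None

    # -- prediction --------------------------------------------------------

    def transform(self, g: GenotypeMatrix) -> np.ndarray:
        """Project new samples into discriminant space using the training
        centering means for imputation and centering."""
        order = {l: i for i, l in enumerate(g.locus_ids)}
        missing_loci = [l for l in self.locus_ids if l not in order]
        if missing_loci:
            raise KeyError(
                f"genotypes lack {len(missing_loci)} model loci, "
                f"e.g. {missing_loci[:5]}"
            )
        if len(g.locus_ids) > len(self.locus_ids):
            warnings.warn(
                f"{len(g.locus_ids) - len(self.locus_ids)} extra loci ignored",
                stacklevel=2,
            )
        sub = g.subset(loci=self.locus_ids)
        calls = sub.calls.astype(float).T
        miss = calls == MISSING
        x = np.where(miss, self.locus_means, calls) - self.locus_means
        return x @ self.loadings @ self.disc_axes

    def predict_membership(self, g: GenotypeMatrix) -> pd.DataFrame:
        """Posterior membership per sample per group (rows sum to 1).

        Isotropic Gaussian in discriminant space with uniform priors:
        posterior_g ∝ exp(-d_g²/2) for the distance d_g to centroid g.
        Samples missing at every model locus get an all-NaN row.
        """
        disc = self.transform(g)
        d2 = (
            ((disc[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        )
        logp = -0.5 * d2
        logp -= logp.max(axis=1, keepdims=True)
        post = np.exp(logp)
        post /= post.sum(axis=1, keepdims=True)
        sub = g.subset(loci=self.locus_ids)
        all_missing = (sub.calls == MISSING).all(axis=0)
        post[all_missing] = np.nan
        return pd.DataFrame(post, index=g.sample_ids, columns=self.groups)

    def reassignment_success(self) -> float:
        """Mean over groups of the fraction of training samples whose argmax
        posterior is their own group."""
        if self.train_disc_scores is None:
            raise ValueError("training scores unavailable (model loaded from JSON)")
        assigned = self.predict_from_disc(self.train_disc_scores)
        truth = np.asarray(self.train_labels, dtype=object)
        per_group = [
            float(np.mean(assigned[truth == gname] == gname))
            for gname in self.groups
        ]
        return float(np.mean(per_group))

    def predict_from_disc(self, disc: np.ndarray) -> np.ndarray:
        d2 = ((disc[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return np.asarray(self.groups, dtype=object)[d2.argmin(axis=1)]

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "DAPC Results",
            "=" * 46,
            f"groups:           {len(self.groups)}",
            f"retained PCs:     {self.n_pca}",
            f"discriminant axes:{self.n_da:>5}",
            f"training samples: {len(self.train_sample_ids)}",
            f"loci:             {len(self.locus_ids)}",
            f"reassignment:     {self.reassignment_success():.3f}",
            "-" * 46,
            "discriminant eigenvalues:",
        ]
        lines += [f"  LD{i + 1}: {ev:.4f}" for i, ev in enumerate(self.eigenvalues)]
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------

    def to_json(self, path=None) -> str:
        doc = {
            "groups": self.groups,
            "n_pca": self.n_pca,
            "n_da": self.n_da,
            "locus_ids": self.locus_ids,
            "locus_means": self.locus_means.tolist(),
            "loadings": self.loadings.tolist(),
            "disc_axes": self.disc_axes.tolist(),
            "centroids": self.centroids.tolist(),
            "eigenvalues": np.asarray(self.eigenvalues).tolist(),
            "train_labels": self.train_labels,
            "train_sample_ids": self.train_sample_ids,
        }
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "DAPCResults":
        if hasattr(source, "read"):
            doc = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                doc = json.loads(text)
            else:
                with open(text) as fh:
                    doc = json.load(fh)
        return cls(
            groups=doc["groups"],
            n_pca=doc["n_pca"],
            n_da=doc["n_da"],
            locus_ids=doc["locus_ids"],
            locus_means=np.asarray(doc["locus_means"]),
            loadings=np.asarray(doc["loadings"]),
            disc_axes=np.asarray(doc["disc_axes"]),
            centroids=np.asarray(doc["centroids"]),
            eigenvalues=np.asarray(doc["eigenvalues"]),
            train_sample_ids=doc.get("train_sample_ids", []),
            train_labels=doc.get("train_labels", []),
            train_disc_scores=None,
        )


# ---------------------------------------------------------------------------
# Functional wrappers matching the pipeline vocabulary
# ---------------------------------------------------------------------------

def fit_dapc(
    g: GenotypeMatrix, labels, n_pca: int, n_da: int | None = None
) -> DAPCResults:
    """Convenience wrapper: ``DAPC(g, labels).fit(n_pca, n_da)``."""
    return DAPC(g, labels).fit(n_pca=n_pca, n_da=n_da)


def predict_membership(m: DAPCResults, g: GenotypeMatrix) -> pd.DataFrame:
    return m.predict_membership(g)


def xval_npca(g, labels, grid, training_fraction=0.75, reps=100, seed=0):
    return DAPC(g, labels).xval_npca(grid, training_fraction, reps, seed)


def optimize_a_score(g, labels, grid, n_perm=10, seed=0):
    return DAPC(g, labels).optimize_a_score(grid, n_perm, seed)


def kmeans_bic(g, k_range=range(1, 41), n_start=1000, n_pca=None, seed=0):
    return DAPC(g).kmeans_bic(k_range, n_start, n_pca, seed)
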