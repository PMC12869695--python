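"""Downstream patient-level analyses of a trained synergy predictor.

* Build a patient x combination matrix of predicted synergy
  probabilities for an anchor drug against a partner library, with the
  "effective" rule: predicted probability > 0.5.
* Split patients into responsive / non-responsive groups by hierarchical
  clustering of the prediction matrix and compare their survival with a
  log-rank test.
* Fit and apply a linear-predictor-score (LPS) classifier: per-gene
  two-sample t-statistics weight a linear score that is classified by a
  two-Gaussian Bayes rule with empirical priors.
* Test whether a drug-target gene set forms a larger connected component
  in the interactome than equally sized random gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import norm, ttest_ind

__all__ = [
    "predict_matrix", "stratify_patients", "logrank_compare",
    "LPSClassifier", "LPSResults", "classify_lps",
    "LccResult", "lcc_permutation_test",
]

EFFECTIVE_THRESHOLD = 0.5


def predict_matrix(results, patients, anchor: str,
                   partners) -> pd.DataFrame:
    """Patient x combination matrix of predicted synergy probabilities.

    `results` is a trained SynergyPredictorResults; `patients` and
    `partners` are id lists known to the model.  Column names are
    "anchor+partner".  The "effective" indicator is matrix > 0.5.
    """
    rows = []
    trips = pd.DataFrame(
        [(anchor, p, s) for s in patients for p in partners],
        columns=["drug_a", "drug_b", "sample_id"])
    probs = results.predict_table(trips).reshape(len(patients),
                                                 len(partners))
    cols = [f"{anchor}+{p}" for p in partners]
    mat = pd.DataFrame(probs, index=list(patients), columns=cols)
    assert ((mat.to_numpy() >= 0) & (mat.to_numpy() <= 1)).all()
    return mat


def rank_partners(matrix: pd.DataFrame) -> pd.Series:
    """Partners ranked by average predicted synergy across samples."""
    return matrix.mean(axis=0).sort_values(ascending=False)


def stratify_patients(matrix: pd.DataFrame, k: int = 2) -> pd.Series:
    """Two-group hierarchical stratification of the prediction matrix.

    Euclidean distance on patient rows, average linkage, cut at k = 2;
    the cluster with the higher grand-mean probability is labeled
    "responsive".  Raises when the matrix carries no structure (all
    rows identical) or fewer than 2 patients.
    """
    if matrix.shape[0] < 2:
        raise ValueError("stratification requires >= 2 patients")
    X = matrix.to_numpy(dtype=float)
    if np.allclose(X, X[0]):
        raise ValueError("identical patient rows: no structure to stratify")
    Z = linkage(X, method="average", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    if len(set(labels)) < 2:
        raise ValueError("clustering produced a single group")
    means = {c: X[labels == c].mean() for c in set(labels)}
    responsive = max(means, key=means.get)
    out = pd.Series(np.where(labels == responsive, "responsive",
                             "non_responsive"), index=matrix.index)
    return out


def logrank_compare(groups: pd.Series, survival: pd.DataFrame):
    """Two-group log-rank test.

    `groups` maps sample -> label; `survival` has columns sample_id,
    time, event.  Returns (chi-squared statistic, p-value).
    """
    surv = survival.set_index("sample_id")
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    idx = [groups.index[groups == g] for g in labels]
    if min(len(i) for i in idx) == 0:
        raise ValueError("one group is empty")
    if min(len(i) for i in idx) < 2:
        raise ValueError("insufficient data: a group has fewer than 2 samples")
    t0, e0 = surv.loc[idx[0], "time"], surv.loc[idx[0], "event"]
    t1, e1 = surv.loc[idx[1], "time"], surv.loc[idx[1], "event"]
    res = logrank_test(t0, t1, event_observed_A=e0, event_observed_B=e1)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------- LPS

@dataclass
class LPSResults:
    """Fitted linear-predictor-score classifier."""
    genes: list
    weights: pd.Series            # per-gene t-statistics
    group_means: dict             # label -> mean LPS
    group_sds: dict               # label -> sd of LPS
    priors: dict                  # label -> empirical proportion
    labels: tuple                 # (group0, group1), sorted
    train_accuracy: float
    val_accuracy: float | None

    def score(self, profile) -> float:
        """LPS(x) = sum_j t_j * x_j over the selected genes."""
        if isinstance(profile, pd.Series):
            missing = [g for g in self.genes if g not in profile.index]
            if missing:
                raise ValueError(f"profile missing LPS genes: {missing[:5]}")
            x = profile.loc[self.genes].to_numpy(dtype=float)
        else:
            x = np.asarray(profile, dtype=float)
            if x.shape[-1] != len(self.genes):
                raise ValueError("profile length != number of LPS genes")
        return float(self.weights.to_numpy() @ x)

    def posterior(self, lps: float) -> float:
        """P(group1 | LPS) from the two fitted Gaussians and priors."""
        g0, g1 = self.labels
        l0 = norm.logpdf(lps, self.group_means[g0], self.group_sds[g0]) \
            + np.log(self.priors[g0])
        l1 = norm.logpdf(lps, self.group_means[g1], self.group_sds[g1]) \
            + np.log(self.priors[g1])
        m = max(l0, l1)
        p1 = np.exp(l1 - m) / (np.exp(l0 - m) + np.exp(l1 - m))
        return float(p1)

    def classify(self, profile, confidence_band: float | None = None):
        """(group, posterior) for one profile.

        Posterior exactly 0.5 breaks toward the first (sorted) group.
        With `confidence_band` (e.g. 0.9), samples whose winning
        posterior falls below the band are returned as "unclassified".
        """
        p1 = self.posterior(self.score(profile))
        group = self.labels[1] if p1 > 0.5 else self.labels[0]
        if confidence_band is not None and max(p1, 1 - p1) < confidence_band:
            return "unclassified", p1
        return group, p1

    def summary(self) -> str:
        lines = [
            f"LPS classifier ({len(self.genes)} genes)",
            "=" * 40,
            f"groups:          {self.labels[0]} vs {self.labels[1]}",
            f"priors:          {self.priors[self.labels[0]]:.2f} / "
            f"{self.priors[self.labels[1]]:.2f}",
            f"LPS means:       {self.group_means[self.labels[0]]:.2f} / "
            f"{self.group_means[self.labels[1]]:.2f}",
            f"train accuracy:  {self.train_accuracy:.3f}",
        ]
        if self.val_accuracy is not None:
            lines.append(f"val accuracy:    {self.val_accuracy:.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"genes": self.genes,
                "weights": self.weights.to_dict(),
                "group_means": self.group_means,
                "group_sds": self.group_sds,
                "priors": self.priors,
                "labels": list(self.labels)}

    @classmethod
    def from_dict(cls, d: dict) -> "LPSResults":
        return cls(genes=list(d["genes"]),
                   weights=pd.Series(d["weights"]).loc[d["genes"]],
                   group_means=dict(d["group_means"]),
                   group_sds=dict(d["group_sds"]),
                   priors=dict(d["priors"]),
                   labels=tuple(d["labels"]),
                   train_accuracy=float(d.get("train_accuracy", np.nan)),
                   val_accuracy=d.get("val_accuracy"))


class LPSClassifier:
    """Model object for the linear-predictor-score construction."""

    def __init__(self, expression: pd.DataFrame, labels: pd.Series,
                 n_genes: int = 50):
        self.expression = expression
        self.labels = labels.loc[expression.index]
        self.n_genes = n_genes
        self.group_names = tuple(sorted(self.labels.unique()))
        if len(self.group_names) != 2:
            raise ValueError("LPS requires exactly two classes")
        for g in self.group_names:
            if (self.labels == g).sum() < 3:
                raise ValueError(f"class {g!r} has fewer than 3 samples")

    def fit(self, train_frac: float = 0.75, seed: int = 0) -> LPSResults:
        """Select genes, fit Gaussians, report train/validation accuracy.

        Gene weights are two-sample t-statistics (group1 - group0)
        computed on the training portion only; the `n_genes` largest
        |t| genes enter the score.
        """
        rng = np.random.default_rng(seed)
        g0, g1 = self.group_names
        # stratified train/validation split
        tr_idx, va_idx = [], []
        for g in self.group_names:
            members = list(self.labels.index[self.labels == g])
            perm = rng.permutation(len(members))
            n_tr = max(2, int(round(train_frac * len(members))))
            tr_idx += [members[i] for i in perm[:n_tr]]
            va_idx += [members[i] for i in perm[n_tr:]]
        Xtr = self.expression.loc[tr_idx]
        ytr = self.labels.loc[tr_idx]

        t = ttest_ind(Xtr[ytr == g1], Xtr[ytr == g0], axis=0).statistic
        t = pd.Series(np.nan_to_num(t), index=self.expression.columns)
        genes = list(t.abs().sort_values(ascending=False)
                     .index[:min(self.n_genes, len(t))])
        weights = t.loc[genes]

        lps_tr = Xtr[genes].to_numpy() @ weights.to_numpy()
        means, sds, priors = {}, {}, {}
        for g in self.group_names:
            vals = lps_tr[(ytr == g).to_numpy()]
            means[g] = float(vals.mean())
            sd = float(vals.std(ddof=1))
            sds[g] = sd if sd > 0 else 1e-6
            priors[g] = float((ytr == g).mean())

        res = LPSResults(genes=genes, weights=weights, group_means=means,
                         group_sds=sds, priors=priors,
                         labels=self.group_names,
                         train_accuracy=np.nan, val_accuracy=None)
        res.train_accuracy = self._accuracy(res, tr_idx)
        res.val_accuracy = (self._accuracy(res, va_idx)
                            if len(va_idx) else None)
        return res

    def _accuracy(self, res: LPSResults, idx) -> float:
        correct = 0
        for s in idx:
            group, _ = res.classify(self.expression.loc[s])
            correct += group == self.labels.loc[s]
        return correct / len(idx)


def classify_lps(model: LPSResults, profile):
    """(group, posterior) for one sample profile."""
    return model.classify(profile)


# ------------------------------------------------------------- LCC test

@dataclass
class LccResult:
    observed_lcc: int
    null_sizes: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    n_dropped: int = 0

    def summary(self) -> str:
        return (f"LCC permutation test: observed {self.observed_lcc}, "
                f"null mean {self.null_sizes.mean():.2f} "
                f"(n_perm={self.n_perm}), p = {self.p_value:.4g}")


def _lcc_size(graph: nx.Graph, nodes) -> int:
    sub = graph.subgraph(nodes)
    if sub.number_of_nodes() == 0:
        return 0
    return max(len(c) for c in nx.connected_components(sub))


def lcc_permutation_test(target_genes, ppi: pd.DataFrame,
                         n_perm: int = 10000, seed: int = 0,
                         degree_matched: bool = False) -> LccResult:
    """Largest-connected-component significance of a gene set.

    The observed statistic is the size of the largest connected
    component of the interactome subgraph induced by `target_genes`.
    The null draws `n_perm` equally sized uniform node sets from the
    full node universe (`degree_matched=True` instead samples within
    degree deciles).  p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    graph = nx.from_pandas_edgelist(ppi, "protein_a", "protein_b")
    universe = sorted(graph.nodes)
    targets = sorted(set(target_genes) & set(universe))
    n_dropped = len(set(target_genes)) - len(targets)
    if not targets:
        raise ValueError("no target genes present in the interactome")
    observed = _lcc_size(graph, targets)

    rng = np.random.default_rng(seed)
    m = len(targets)
    if degree_matched:
        deg = pd.Series({n: graph.degree(n) for n in universe})
        decile = pd.qcut(deg.rank(method="first"), 10, labels=False)
        pools = {d: list(deg.index[decile == d]) for d in range(10)}
        target_dec = decile.loc[targets]
    null = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        if degree_matched:
            draw = [pools[d][rng.integers(len(pools[d]))]
                    for d in target_dec]
        else:
            draw = [universe[j] for j in rng.choice(len(universe), size=m,
                                                    replace=False)]
        null[i] = _lcc_size(graph, draw)
    p = (1 + int((null >= observed).sum())) / (1 + n_perm)
    return LccResult(observed_lcc=observed, null_sizes=null, p_value=p,
                     n_perm=n_perm, seed=seed, n_dropped=n_dropped)
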