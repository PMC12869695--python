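"""Leakage-free data splitting, ranking metrics and cross-validation.

Three split strategies mirror the generalization questions asked of a
synergy predictor:

* leave-combo-out — canonical drug *pairs* are partitioned across folds,
  so a pair never spans folds even when screened in many samples;
* leave-drug-out — drugs are clustered by Tanimoto structural distance
  (agglomerative, average linkage) and a triplet belongs to a fold only
  when *both* its drugs sit in that fold's cluster; cross-cluster
  triplets are dropped so the no-shared-drug guarantee is exact;
* leave-sample-out — samples are clustered by affinity propagation on
  the top-1,000 most variable genes; the largest cluster trains, the
  rest test.

Every plan re-asserts its own disjointness guarantees on construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from sklearn.cluster import AffinityPropagation
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "SplitPlan", "split_leave_combo_out", "split_leave_drug_out",
    "split_leave_sample_out", "auroc", "auprc", "spearman",
    "cross_validate", "CrossValidationResults",
]


def _canonical_pairs(triplets: pd.DataFrame) -> pd.Series:
    a = triplets["drug_a"].to_numpy()
    b = triplets["drug_b"].to_numpy()
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    return pd.Series([f"{x}|{y}" for x, y in zip(lo, hi)],
                     index=triplets.index)


@dataclass
class SplitPlan:
    strategy: str
    folds: list                      # [{"train": idx, "val": idx, "test": idx}]
    seed: int
    n_dropped: int = 0
    provenance: dict = field(default_factory=dict)
    triplets: pd.DataFrame | None = None

    def __post_init__(self):
        if self.triplets is not None:
            self.assert_disjoint(self.triplets)

    def assert_disjoint(self, triplets: pd.DataFrame) -> None:
        """Strategy-specific leakage assertions; raises on violation."""
        pairs = _canonical_pairs(triplets)
        test_union = set()
        for fold in self.folds:
            tr = np.asarray(fold["train"], dtype=int)
            va = np.asarray(fold["val"], dtype=int)
            te = np.asarray(fold["test"], dtype=int)
            assert not (set(tr) & set(te)), "train/test rows overlap"
            assert not (set(va) & set(te)), "val/test rows overlap"
            assert not (set(tr) & set(va)), "train/val rows overlap"
            assert not (set(te) & test_union), "test folds overlap"
            test_union |= set(te)
            fit_idx = np.concatenate([tr, va])
            if self.strategy == "leave_combo_out":
                assert not (set(pairs.iloc[fit_idx]) & set(pairs.iloc[te])), \
                    "a drug pair spans train and test"
            elif self.strategy == "leave_drug_out":
                fit_drugs = set(triplets["drug_a"].iloc[fit_idx]) | \
                    set(triplets["drug_b"].iloc[fit_idx])
                te_drugs = set(triplets["drug_a"].iloc[te]) | \
                    set(triplets["drug_b"].iloc[te])
                assert not (fit_drugs & te_drugs), \
                    "a drug spans train and test"
            elif self.strategy == "leave_sample_out":
                assert not (set(triplets["sample_id"].iloc[fit_idx])
                            & set(triplets["sample_id"].iloc[te])), \
                    "a sample spans train and test"

    def to_dict(self) -> dict:
        return {"strategy": self.strategy, "seed": self.seed,
                "n_dropped": self.n_dropped,
                "folds": [{k: [int(i) for i in v] for k, v in f.items()}
                          for f in self.folds]}


def _train_val(rng, idx, val_frac=0.1):
    idx = np.asarray(idx, dtype=int)
    perm = rng.permutation(len(idx))
    n_val = max(1, int(round(val_frac * len(idx))))
    return idx[perm[n_val:]], idx[perm[:n_val]]


def split_leave_combo_out(triplets: pd.DataFrame, k: int = 5,
                          seed: int = 0) -> SplitPlan:
    """Partition canonical drug pairs into k balanced folds."""
    rng = np.random.default_rng(seed)
    pairs = _canonical_pairs(triplets)
    uniq = sorted(pairs.unique())
    if len(uniq) < k:
        raise ValueError(f"need >= {k} distinct drug pairs, got {len(uniq)}")
    order = rng.permutation(len(uniq))
    fold_of_pair = {uniq[j]: i % k for i, j in enumerate(order)}
    fold_rows = [np.flatnonzero(pairs.map(fold_of_pair).to_numpy() == f)
                 for f in range(k)]
    folds = []
    for f in range(k):
        test = fold_rows[f]
        nominal = np.concatenate([fold_rows[g] for g in range(k) if g != f])
        train, val = _train_val(rng, nominal)
        folds.append({"train": train, "val": val, "test": test})
    return SplitPlan(strategy="leave_combo_out", folds=folds, seed=seed,
                     triplets=triplets,
                     provenance={"n_pairs": len(uniq)})


def split_leave_drug_out(triplets: pd.DataFrame, drug_fingerprints: dict,
                         k: int = 5, seed: int = 0) -> SplitPlan:
    """Cluster drugs on Tanimoto distance; fold = within-cluster triplets.

    `drug_fingerprints` maps drug id -> Fingerprint.  Triplets whose two
    drugs land in different clusters are dropped from every fold (the
    only choice that keeps the no-shared-drug guarantee exact) and
    counted in the plan.
    """
    from .harmonize import tanimoto
    drugs = sorted(set(triplets["drug_a"]) | set(triplets["drug_b"]))
    missing = [d for d in drugs if d not in drug_fingerprints]
    if missing:
        raise ValueError(f"missing fingerprints for {missing[:5]}")
    if len(drugs) < k:
        raise ValueError(f"need >= {k} drugs, got {len(drugs)}")
    n = len(drugs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - tanimoto(drug_fingerprints[drugs[i]],
                               drug_fingerprints[drugs[j]])
            dist[i, j] = dist[j, i] = d
    if dist.max() == 0.0:
        raise ValueError("all drugs are structurally identical; clustering "
                         "is degenerate — use leave-combo-out instead")
    Z = linkage(squareform(dist, checks=False), method="average")
    cluster = fcluster(Z, t=k, criterion="maxclust") - 1
    cluster_of = {d: int(c) for d, c in zip(drugs, cluster)}

    rng = np.random.default_rng(seed)
    ca = triplets["drug_a"].map(cluster_of).to_numpy()
    cb = triplets["drug_b"].map(cluster_of).to_numpy()
    same = ca == cb
    n_dropped = int((~same).sum())
    folds = []
    for f in range(k):
        test = np.flatnonzero(same & (ca == f))
        nominal = np.flatnonzero(same & (ca != f))
        if len(test) == 0 or len(nominal) == 0:
            continue       # a cluster without within-cluster pairs
        train, val = _train_val(rng, nominal)
        folds.append({"train": train, "val": val, "test": test})
    if not folds:
        raise ValueError("no usable leave-drug-out folds; clusters contain "
                         "no within-cluster pairs")
    return SplitPlan(strategy="leave_drug_out", folds=folds, seed=seed,
                     n_dropped=n_dropped, triplets=triplets,
                     provenance={"clusters": cluster_of})


def _kmedoids(D: np.ndarray, k: int, rng, n_iter: int = 100) -> np.ndarray:
    """Small PAM-style k-medoids on a distance matrix (fallback path)."""
    n = D.shape[0]
    medoids = rng.choice(n, size=k, replace=False)
    for _ in range(n_iter):
        assign = np.argmin(D[:, medoids], axis=1)
        new = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(assign == c)
            if len(members):
                within = D[np.ix_(members, members)].sum(axis=1)
                new[c] = members[np.argmin(within)]
        if np.array_equal(new, medoids):
            break
        medoids = new
    return np.argmin(D[:, medoids], axis=1)


def split_leave_sample_out(triplets: pd.DataFrame, expression: pd.DataFrame,
                           seed: int = 0, n_top_genes: int = 1000,
                           val_frac: float = 0.1) -> SplitPlan:
    """Affinity-propagation sample clusters; largest cluster trains.

    Similarity is the negative squared Euclidean distance over the top
    `n_top_genes` most variable genes (all genes when fewer exist).
    On non-convergence, falls back to k-medoids with k = 4 (logged in
    provenance).
    """
    samples = sorted(set(triplets["sample_id"]))
    missing = [s for s in samples if s not in expression.index]
    if missing:
        raise ValueError(f"missing expression for samples {missing[:5]}")
    if len(samples) < 4:
        raise ValueError("leave-sample-out requires >= 4 samples")
    X = expression.loc[samples]
    var = X.var(axis=0, ddof=1)
    top = var.sort_values(ascending=False).index[:min(n_top_genes,
                                                      X.shape[1])]
    X = X[top].to_numpy(dtype=float)

    method = "affinity_propagation"
    with warnings.catch_warnings():
        warnings.simplefilter("error")   # surface the non-convergence warning
        try:
            ap = AffinityPropagation(damping=0.9, max_iter=1000,
                                     random_state=seed).fit(X)
            labels = ap.labels_
            if len(set(labels)) < 2 or np.any(labels < 0):
                raise RuntimeError("degenerate clustering")
        except Exception:
            method = "kmedoids_fallback"
            D = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=-1)
            labels = _kmedoids(D, k=4, rng=np.random.default_rng(seed))

    counts = pd.Series(labels).value_counts()
    biggest = counts.idxmax()
    train_samples = {samples[i] for i in range(len(samples))
                     if labels[i] == biggest}
    test_samples = set(samples) - train_samples
    if not test_samples:
        raise ValueError("all samples fell in one cluster; no test samples "
                         "— use another split strategy")
    in_train = triplets["sample_id"].isin(train_samples).to_numpy()
    nominal = np.flatnonzero(in_train)
    test = np.flatnonzero(~in_train)
    rng = np.random.default_rng(seed)
    train, val = _train_val(rng, nominal, val_frac)
    return SplitPlan(strategy="leave_sample_out",
                     folds=[{"train": train, "val": val, "test": test}],
                     seed=seed, triplets=triplets,
                     provenance={"method": method,
                                 "n_clusters": int(len(counts)),
                                 "train_samples": sorted(train_samples)})


# ----------------------------------------------------------------- metrics

def _check_two_class(labels):
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("metric requires both classes present")
    return labels


def auroc(labels, scores) -> float:
    """P(random positive outranks random negative), ties counted 1/2."""
    labels = _check_two_class(labels)
    return float(roc_auc_score(labels, scores))


def auprc(labels, scores) -> float:
    """Step-integrated precision-recall area (average precision)."""
    labels = _check_two_class(labels)
    return float(average_precision_score(labels, scores))


def spearman(x, y) -> float:
    """Rank correlation with average-rank tie handling."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("spearman requires n >= 3")
    rho = spearmanr(x, y).statistic
    return float(rho) if np.isfinite(rho) else 0.0


# --------------------------------------------------------- cross-validation

@dataclass
class CrossValidationResults:
    strategy: str
    per_fold: pd.DataFrame      # fold, n_test, auroc, auprc, spearman
    plan: SplitPlan
    fold_results: list = field(default_factory=list)

    def aggregate(self) -> pd.DataFrame:
        """Mean +/- sd across folds (the conventional "0.855±0.004" shape)."""
        cols = [c for c in ("auroc", "auprc", "spearman")
                if c in self.per_fold.columns]
        return pd.DataFrame({"mean": self.per_fold[cols].mean(),
                             "sd": self.per_fold[cols].std(ddof=1)})

    def summary(self) -> str:
        agg = self.aggregate()
        lines = [f"{len(self.per_fold)}-fold cross-validation "
                 f"({self.strategy})", "=" * 44]
        for m, row in agg.iterrows():
            sd = 0.0 if np.isnan(row['sd']) else row['sd']
            lines.append(f"{m:>9}: {row['mean']:.3f} ± {sd:.3f}")
        return "\n".join(lines)


def cross_validate(model_cfg, triplets: pd.DataFrame, features,
                   strategy: str = "leave_combo_out", k: int = 5,
                   seed: int = 0, keep_models: bool = False,
                   verbose: bool = False) -> CrossValidationResults:
    """Train one predictor per fold and report ranking metrics.

    `features` is a FeatureSet; leave_drug_out derives fingerprints from
    it, leave_sample_out clusters on its expression table.
    """
    from .harmonize import Fingerprint
    from .model import SynergyPredictor

    if strategy == "leave_combo_out":
        plan = split_leave_combo_out(triplets, k=k, seed=seed)
    elif strategy == "leave_drug_out":
        fps = {d: Fingerprint(
            bits=tuple(np.flatnonzero(features.fingerprints.loc[d].to_numpy())),
            n_bits=features.fingerprints.shape[1])
            for d in features.fingerprints.index}
        plan = split_leave_drug_out(triplets, fps, k=k, seed=seed)
    elif strategy == "leave_sample_out":
        plan = split_leave_sample_out(triplets, features.expression,
                                      seed=seed)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    rows, kept = [], []
    for f, fold in enumerate(plan.folds):
        model = SynergyPredictor(triplets, features, model_cfg)
        res = model.fit(split=fold, seed=seed + f)
        try:
            metrics = res.evaluate(fold["test"])
        except ValueError:       # one-class test fold
            metrics = {"n": len(fold["test"]), "auroc": np.nan,
                       "auprc": np.nan}
        rows.append({"fold": f, "n_test": metrics["n"],
                     "auroc": metrics.get("auroc", np.nan),
                     "auprc": metrics.get("auprc", np.nan),
                     "spearman": metrics.get("spearman", np.nan)})
        if verbose:
            print(f"fold {f}: {rows[-1]}")
        if keep_models:
            kept.append(res)
    return CrossValidationResults(strategy=strategy,
                                  per_fold=pd.DataFrame(rows), plan=plan,
                                  fold_results=kept)
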