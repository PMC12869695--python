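"""Attention-fusion synergy predictor (Model -> fit() -> Results).

The predictor ingests triplets (drug_a, drug_b, sample, label) plus a
:class:`~combosyn.features.FeatureSet` and learns a binary synergy
probability from five branch embeddings: two chemical-fingerprint
tokens, two propagated drug-target tokens and one transcriptome token.
Tokens of a common width d are fused by scaled dot-product attention
(softmax(QK^T/sqrt(d_k))V), flattened, and passed through a ReLU MLP
head ending in a single sigmoid unit.  Training minimizes binary
cross-entropy with adaptive-moment gradient descent; validation AUROC is
logged each epoch and the best-validation epoch's weights are kept.

Variants: a mutation-profile sample branch, a chemistry-ablated model
(three tokens), and probability-averaging ensembles.

Desk-scale defaults (token width 64) keep training at minutes on one
CPU; the full-scale configuration described in docs/methods.md uses
token width 256 and a 500-feature drug-target bottleneck.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._autodiff import Adam, Tensor, stack
from .features import (AutoencoderConfig, ExpressionEncoder, FeatureSet,
                       pretrain_autoencoder)

__all__ = [
    "ModelConfig", "FusionState", "AttentionBlock", "attention_fuse",
    "bce_loss", "SynergyPredictor", "SynergyPredictorResults",
    "train_variant", "ensemble", "save_checkpoint", "load_checkpoint",
]

_CLIP = 1e-7


@dataclass(frozen=True)
class ModelConfig:
    token_dim: int = 64          # common token width d (256 at full scale)
    head_dim: int = 32           # attention head width d_k
    chem_hidden: int = 128
    dti_channels: int = 8
    dti_kernel: int = 8
    dti_stride: int = 4
    dti_mid: int = 500           # compressed drug-target width
    head_widths: tuple = (512, 128)
    lr: float = 1e-3
    batch_size: int = 128
    epochs: int = 20
    val_frac: float = 0.1
    use_chem: bool = True
    use_dti: bool = True
    use_sample: bool = True
    sample_source: str = "expression"    # or "mutation"
    freeze_sample_encoder: bool = False
    mask_self_modality: bool = False
    pretrain: AutoencoderConfig = field(default_factory=AutoencoderConfig)
    seed: int = 0

    def with_(self, **kw) -> "ModelConfig":
        return replace(self, **kw)


@dataclass
class FusionState:
    """The branch embeddings entering/leaving the attention layer."""
    tokens: np.ndarray    # n_tokens x d

    def __post_init__(self):
        self.tokens = np.atleast_2d(np.asarray(self.tokens, dtype=float))
        if not np.all(np.isfinite(self.tokens)):
            raise ValueError("non-finite token values")


@dataclass
class AttentionBlock:
    Wq: np.ndarray   # d x d_k
    Wk: np.ndarray
    Wv: np.ndarray
    Wo: np.ndarray   # d_k x d


def attention_fuse(state: FusionState, block: AttentionBlock,
                   mask: np.ndarray | None = None) -> FusionState:
    """One round of scaled dot-product self-attention over the tokens.

    A = softmax(QK^T / sqrt(d_k)) row-wise; output = (A V) Wo, one
    updated token per input token, widths preserved by the output map.
    """
    X = state.tokens
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite token values")
    Q, K, V = X @ block.Wq, X @ block.Wk, X @ block.Wv
    dk = block.Wq.shape[1]
    logits = Q @ K.T / np.sqrt(dk)
    if mask is not None:
        logits = np.where(mask, logits, -1e30)
    logits = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(logits)
    A = e / e.sum(axis=-1, keepdims=True)
    return FusionState(tokens=(A @ V) @ block.Wo)


def bce_loss(labels, probs) -> float:
    """Mean binary cross-entropy with probabilities clipped to
    [1e-7, 1-1e-7] before the logs."""
    p = np.asarray(labels, dtype=float)
    q = np.clip(np.asarray(probs, dtype=float), _CLIP, 1 - _CLIP)
    return float(-np.mean(p * np.log(q) + (1 - p) * np.log(1 - q)))


def _init(rng, n_in, n_out):
    W = Tensor(rng.normal(0, np.sqrt(2.0 / n_in), (n_in, n_out)),
               requires_grad=True)
    b = Tensor(np.zeros(n_out), requires_grad=True)
    return W, b


class _Network:
    """Parameter container + batched autodiff forward pass."""

    def __init__(self, cfg: ModelConfig, n_bits: int, n_genes: int,
                 n_sample_features: int, rng: np.random.Generator,
                 sample_encoder_init: ExpressionEncoder | None = None):
        self.cfg = cfg
        self.params: list[Tensor] = []
        d = cfg.token_dim

        def add(*ts):
            self.params.extend(ts)
            return ts

        if cfg.use_chem:
            self.chem1 = add(*_init(rng, n_bits, cfg.chem_hidden))
            self.chem2 = add(*_init(rng, cfg.chem_hidden, d))
        if cfg.use_dti:
            self.convW = Tensor(rng.normal(
                0, np.sqrt(2.0 / cfg.dti_kernel),
                (cfg.dti_kernel, cfg.dti_channels)), requires_grad=True)
            self.convb = Tensor(np.zeros(cfg.dti_channels), requires_grad=True)
            self.params.extend([self.convW, self.convb])
            L = (n_genes - cfg.dti_kernel) // cfg.dti_stride + 1
            self.dti_flat = L * cfg.dti_channels
            self.dti1 = add(*_init(rng, self.dti_flat, cfg.dti_mid))
            self.dti2 = add(*_init(rng, cfg.dti_mid, d))
        if cfg.use_sample:
            if sample_encoder_init is not None:
                W1, b1, W2, b2 = sample_encoder_init.weights[:4]
                req = not cfg.freeze_sample_encoder
                self.enc1 = (Tensor(W1.copy(), requires_grad=req),
                             Tensor(b1.copy(), requires_grad=req))
                self.enc2 = (Tensor(W2.copy(), requires_grad=req),
                             Tensor(b2.copy(), requires_grad=req))
                bottleneck = W2.shape[1]
                if req:
                    self.params.extend([*self.enc1, *self.enc2])
            else:
                h = max(16, n_sample_features // 2)
                bottleneck = max(8, n_sample_features // 4)
                self.enc1 = add(*_init(rng, n_sample_features, h))
                self.enc2 = add(*_init(rng, h, bottleneck))
            self.samp_proj = add(*_init(rng, bottleneck, d))

        # attention projections are pure linear maps (no bias)
        self.att = {}
        for k in ("Wq", "Wk", "Wv"):
            self.att[k] = Tensor(rng.normal(0, np.sqrt(1.0 / d),
                                            (d, cfg.head_dim)),
                                 requires_grad=True)
        self.att["Wo"] = Tensor(rng.normal(0, np.sqrt(1.0 / cfg.head_dim),
                                           (cfg.head_dim, d)),
                                requires_grad=True)
        self.params.extend(self.att.values())

        n_tok = (2 if cfg.use_chem else 0) + (2 if cfg.use_dti else 0) \
            + (1 if cfg.use_sample else 0)
        self.n_tokens = n_tok
        widths = (n_tok * d, *cfg.head_widths, 1)
        self.head = []
        for a, b in zip(widths[:-1], widths[1:]):
            self.head.append(add(*_init(rng, a, b)))

        if cfg.mask_self_modality:
            groups = []
            if cfg.use_chem:
                groups += [0, 0]
            if cfg.use_dti:
                groups += [1, 1]
            if cfg.use_sample:
                groups += [2]
            g = np.array(groups)
            self.att_mask = (g[:, None] != g[None, :])
            if not self.att_mask.any(axis=1).all():
                self.att_mask = None   # degenerate: would mask everything
        else:
            self.att_mask = None

    def _encode_chem(self, fp: np.ndarray) -> Tensor:
        h = (Tensor(fp) @ self.chem1[0] + self.chem1[1]).relu()
        return h @ self.chem2[0] + self.chem2[1]

    def _encode_dti(self, prop: np.ndarray) -> Tensor:
        cfg = self.cfg
        win = Tensor(prop).unfold(cfg.dti_kernel, cfg.dti_stride)  # B,L,K
        conv = (win @ self.convW + self.convb).relu()              # B,L,C
        flat = conv.reshape(prop.shape[0], self.dti_flat)
        h = (flat @ self.dti1[0] + self.dti1[1]).relu()
        return h @ self.dti2[0] + self.dti2[1]

    def _encode_sample(self, x: np.ndarray) -> Tensor:
        h = (Tensor(x) @ self.enc1[0] + self.enc1[1]).relu()
        z = h @ self.enc2[0] + self.enc2[1]
        return z @ self.samp_proj[0] + self.samp_proj[1]

    def forward(self, fp_a, fp_b, dti_a, dti_b, samp) -> Tensor:
        """Batched probability: tokens -> attention -> flatten -> MLP."""
        cfg = self.cfg
        tokens = []
        if cfg.use_chem:
            tokens += [self._encode_chem(fp_a), self._encode_chem(fp_b)]
        if cfg.use_dti:
            tokens += [self._encode_dti(dti_a), self._encode_dti(dti_b)]
        if cfg.use_sample:
            tokens.append(self._encode_sample(samp))
        X = stack(tokens, axis=1)                      # B, T, d
        Q = X @ self.att["Wq"]
        K = X @ self.att["Wk"]
        V = X @ self.att["Wv"]
        logits = (Q @ K.transpose_last()) * (1.0 / np.sqrt(cfg.head_dim))
        if self.att_mask is not None:
            penalty = np.where(self.att_mask, 0.0, -1e30)
            logits = logits + Tensor(penalty[None, :, :])
        A = logits.softmax(axis=-1)
        fused = (A @ V) @ self.att["Wo"]               # B, T, d
        h = fused.reshape(fused.shape[0], self.n_tokens * cfg.token_dim)
        for k, (W, b) in enumerate(self.head):
            h = h @ W + b
            if k < len(self.head) - 1:
                h = h.relu()
        return h.reshape(h.shape[0]).sigmoid()

    def loss(self, batches, labels) -> Tensor:
        prob = self.forward(*batches).clip(_CLIP, 1 - _CLIP)
        y = Tensor(np.asarray(labels, dtype=float))
        ll = y * prob.log() + (1.0 - y) * (1.0 - prob).log()
        return -ll.mean()

    def get_weights(self):
        return [p.data.copy() for p in self.params]

    def set_weights(self, weights):
        for p, w in zip(self.params, weights):
            p.data = w.copy()

    def named_tensors(self) -> dict:
        """Role-keyed view of every tensor (incl. frozen encoders)."""
        cfg, out = self.cfg, {}
        if cfg.use_chem:
            out.update(chem1W=self.chem1[0], chem1b=self.chem1[1],
                       chem2W=self.chem2[0], chem2b=self.chem2[1])
        if cfg.use_dti:
            out.update(convW=self.convW, convb=self.convb,
                       dti1W=self.dti1[0], dti1b=self.dti1[1],
                       dti2W=self.dti2[0], dti2b=self.dti2[1])
        if cfg.use_sample:
            out.update(enc1W=self.enc1[0], enc1b=self.enc1[1],
                       enc2W=self.enc2[0], enc2b=self.enc2[1],
                       projW=self.samp_proj[0], projb=self.samp_proj[1])
        out.update({k: v for k, v in self.att.items()})
        for i, (W, b) in enumerate(self.head):
            out[f"head{i}W"] = W
            out[f"head{i}b"] = b
        return out


class SynergyPredictor:
    """Synergy model built from a triplet table and a FeatureSet.

    Parameters
    ----------
    triplets : DataFrame with columns drug_a, drug_b, sample_id, label
        (an optional `score` column is carried through for correlation
        metrics).
    features : FeatureSet
        Per-drug fingerprints and propagated target vectors, per-sample
        expression (and optionally mutation) profiles.
    config : ModelConfig
    """

    def __init__(self, triplets: pd.DataFrame, features: FeatureSet,
                 config: ModelConfig | None = None):
        self.triplets = triplets.reset_index(drop=True)
        self.features = features
        self.config = config or ModelConfig()
        for col in ("drug_a", "drug_b", "sample_id", "label"):
            if col not in self.triplets.columns:
                raise ValueError(f"triplet table lacks column {col!r}")
        drugs = set(features.fingerprints.index) & set(
            features.dti_propagated.index)
        used = set(self.triplets["drug_a"]) | set(self.triplets["drug_b"])
        if not used <= drugs:
            raise ValueError(f"missing drug features for {sorted(used - drugs)[:5]}")
        sample_table = (features.mutation
                        if self.config.sample_source == "mutation"
                        else features.expression)
        if sample_table is None:
            raise ValueError(
                f"feature set has no {self.config.sample_source} table")
        missing = set(self.triplets["sample_id"]) - set(sample_table.index)
        if missing:
            raise ValueError(f"missing sample profiles for {sorted(missing)[:5]}")

    @classmethod
    def from_world(cls, world, n_pairs: int = 100,
                   config: ModelConfig | None = None, **feature_kw):
        """Convenience constructor straight from a synthetic world."""
        from .features import build_features
        from .synth import make_triplets
        feats = build_features(world, **feature_kw)
        trips = make_triplets(world, n_pairs=n_pairs)
        return cls(trips, feats, config)

    # ------------------------------------------------------------ fitting
    def _entity_arrays(self, train_samples):
        feats, cfg = self.features, self.config
        fp = feats.fingerprints
        prop = feats.dti_propagated
        # scale propagated rows to unit max so conv inputs are O(1)
        pmax = prop.to_numpy().max()
        prop = prop / (pmax if pmax > 0 else 1.0)
        table = (feats.mutation if cfg.sample_source == "mutation"
                 else feats.expression)
        mu = table.loc[train_samples].mean(axis=0).to_numpy()
        sd = table.loc[train_samples].std(axis=0, ddof=0).to_numpy()
        sd[sd == 0] = 1.0
        samp = (table.to_numpy(dtype=float) - mu) / sd
        samp = pd.DataFrame(samp, index=table.index, columns=table.columns)
        return fp, prop, samp, (mu, sd)

    def build_network(self, seed: int | None = None,
                      train_samples=None) -> _Network:
        """Initialize a network (optionally warm-starting the sample
        branch from an autoencoder pre-trained on `train_samples`)."""
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        feats = self.features
        table = (feats.mutation if cfg.sample_source == "mutation"
                 else feats.expression)
        encoder = None
        if train_samples is not None and len(train_samples) >= 10:
            encoder = pretrain_autoencoder(
                table.loc[train_samples],
                replace(cfg.pretrain, seed=seed))
        return _Network(cfg, feats.fingerprints.shape[1],
                        feats.dti_propagated.shape[1], table.shape[1],
                        rng, sample_encoder_init=encoder)

    def fit(self, split: dict | None = None, seed: int | None = None,
            verbose: bool = False) -> "SynergyPredictorResults":
        """Train on the (train, val) portion of `split`.

        `split` maps "train"/"val"/(optionally) "test" to triplet row
        indices; when omitted, a seeded 90/10 train/validation split of
        all rows is used.  Returns a Results object carrying the
        best-validation-epoch weights and the full training log.
        """
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        n = len(self.triplets)
        if split is None:
            perm = rng.permutation(n)
            n_val = max(1, int(round(cfg.val_frac * n)))
            split = {"train": perm[n_val:], "val": perm[:n_val]}
        train_idx = np.asarray(split["train"], dtype=int)
        val_idx = np.asarray(split["val"], dtype=int)
        if len(train_idx) == 0 or len(val_idx) == 0:
            raise ValueError("empty train or validation set")
        y_train = self.triplets["label"].to_numpy()[train_idx]
        if len(np.unique(y_train)) < 2:
            raise ValueError("training labels are all one class")

        train_samples = sorted(
            set(self.triplets["sample_id"].iloc[train_idx]))
        fp, prop, samp, samp_stats = self._entity_arrays(train_samples)
        net = self.build_network(seed=seed, train_samples=train_samples)
        opt = Adam(net.params, lr=cfg.lr)

        di = {d: i for i, d in enumerate(fp.index)}
        si = {s: i for i, s in enumerate(samp.index)}
        fpA = fp.to_numpy(dtype=float)
        prA = prop.to_numpy(dtype=float)
        smA = samp.to_numpy(dtype=float)
        a_all = self.triplets["drug_a"].map(di).to_numpy()
        b_all = self.triplets["drug_b"].map(di).to_numpy()
        s_all = self.triplets["sample_id"].map(si).to_numpy()
        y_all = self.triplets["label"].to_numpy(dtype=float)

        from .evaluate import auroc

        def predict_idx(idx):
            a, b, s = a_all[idx], b_all[idx], s_all[idx]
            p1 = net.forward(fpA[a], fpA[b], prA[a], prA[b], smA[s]).data
            p2 = net.forward(fpA[b], fpA[a], prA[b], prA[a], smA[s]).data
            return 0.5 * (p1 + p2)

        log = []
        best = (-np.inf, net.get_weights(), -1)
        for epoch in range(cfg.epochs):
            order = rng.permutation(train_idx)
            flip = rng.random(len(order)) < 0.5   # pair-order augmentation
            losses = []
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                fl = flip[start:start + cfg.batch_size]
                a = np.where(fl, b_all[idx], a_all[idx])
                b = np.where(fl, a_all[idx], b_all[idx])
                s = s_all[idx]
                opt.zero_grad()
                loss = net.loss((fpA[a], fpA[b], prA[a], prA[b], smA[s]),
                                y_all[idx])
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            val_scores = predict_idx(val_idx)
            try:
                val_auc = auroc(y_all[val_idx], val_scores)
            except ValueError:
                val_auc = np.nan
            log.append((epoch, float(np.mean(losses)), val_auc))
            if verbose:
                print(f"epoch {epoch}: loss {np.mean(losses):.4f} "
                      f"val AUROC {val_auc:.3f}")
            if np.isnan(val_auc) or val_auc > best[0]:
                best = (val_auc, net.get_weights(), epoch)
        net.set_weights(best[1])
        return SynergyPredictorResults(
            model=self, network=net, split=split,
            sample_stats=samp_stats,
            entity_arrays=(fpA, prA, smA, di, si),
            training_log=pd.DataFrame(
                log, columns=["epoch", "train_loss", "val_auroc"]),
            best_epoch=best[2], seed=seed)


class SynergyPredictorResults:
    """Trained synergy predictor: weights, log, predictions, diagnostics."""

    def __init__(self, model, network, split, sample_stats, entity_arrays,
                 training_log, best_epoch, seed):
        self.model = model
        self.network = network
        self.split = split
        self.sample_stats = sample_stats
        self._fpA, self._prA, self._smA, self._di, self._si = entity_arrays
        self.training_log = training_log
        self.best_epoch = best_epoch
        self.seed = seed

    @property
    def config(self) -> ModelConfig:
        return self.model.config

    # --------------------------------------------------------- prediction
    def _predict_rows(self, a_idx, b_idx, s_idx) -> np.ndarray:
        net = self.network
        p1 = net.forward(self._fpA[a_idx], self._fpA[b_idx],
                         self._prA[a_idx], self._prA[b_idx],
                         self._smA[s_idx]).data
        p2 = net.forward(self._fpA[b_idx], self._fpA[a_idx],
                         self._prA[b_idx], self._prA[a_idx],
                         self._smA[s_idx]).data
        return 0.5 * (p1 + p2)

    def predict(self, drug_a, drug_b, sample) -> float:
        """Symmetrized synergy probability for one triplet."""
        a = np.array([self._di[drug_a]])
        b = np.array([self._di[drug_b]])
        s = np.array([self._si[sample]])
        return float(self._predict_rows(a, b, s)[0])

    def predict_table(self, triplets: pd.DataFrame) -> np.ndarray:
        a = triplets["drug_a"].map(self._di).to_numpy()
        b = triplets["drug_b"].map(self._di).to_numpy()
        s = triplets["sample_id"].map(self._si).to_numpy()
        if np.any(pd.isna(a)) or np.any(pd.isna(b)) or np.any(pd.isna(s)):
            raise ValueError("triplet table references unknown entities")
        out = np.empty(len(triplets))
        for start in range(0, len(triplets), 1024):
            sl = slice(start, start + 1024)
            out[sl] = self._predict_rows(a[sl].astype(int),
                                         b[sl].astype(int),
                                         s[sl].astype(int))
        return out

    def classify(self, drug_a, drug_b, sample) -> int:
        """Synergistic iff predicted probability strictly exceeds 0.5."""
        return int(self.predict(drug_a, drug_b, sample) > 0.5)

    def compress_targets(self, propagated_row) -> np.ndarray:
        """Compressed drug-target embedding (the DTI branch's
        intermediate layer, 500 features by default)."""
        net, cfg = self.network, self.config
        if not cfg.use_dti:
            raise RuntimeError("DTI branch is disabled in this model")
        x = np.atleast_2d(np.asarray(propagated_row, dtype=float))
        win = Tensor(x).unfold(cfg.dti_kernel, cfg.dti_stride)
        conv = (win @ net.convW + net.convb).relu()
        flat = conv.reshape(x.shape[0], net.dti_flat)
        h = (flat @ net.dti1[0] + net.dti1[1]).relu()
        return h.data[0]

    # --------------------------------------------------------- evaluation
    def evaluate(self, idx=None) -> dict:
        """AUROC/AUPRC (and Spearman when a score column exists) on the
        given triplet rows (defaults to the split's test set)."""
        from .evaluate import auprc, auroc, spearman
        if idx is None:
            idx = self.split.get("test")
        if idx is None:
            raise ValueError("no test indices available")
        idx = np.asarray(idx, dtype=int)
        sub = self.model.triplets.iloc[idx]
        scores = self.predict_table(sub)
        y = sub["label"].to_numpy()
        out = {"n": len(idx), "auroc": auroc(y, scores),
               "auprc": auprc(y, scores)}
        score_col = next((c for c in ("score", "score_loewe")
                          if c in sub.columns), None)
        if score_col is not None and len(idx) >= 3:
            out["spearman"] = spearman(sub[score_col].to_numpy(), scores)
        return out

    def summary(self) -> str:
        cfg = self.config
        n_par = sum(p.data.size for p in self.network.params)
        lines = [
            "Synergy predictor results",
            "=" * 48,
            f"tokens:            {self.network.n_tokens} x d={cfg.token_dim}",
            f"sample branch:     {cfg.sample_source}"
            + (" (frozen)" if cfg.freeze_sample_encoder else ""),
            f"parameters:        {n_par}",
            f"training triplets: {len(self.split['train'])}",
            f"validation:        {len(self.split['val'])}",
            f"epochs trained:    {len(self.training_log)}"
            f" (best epoch {self.best_epoch})",
            f"best val AUROC:    "
            f"{self.training_log['val_auroc'].max():.3f}",
            f"final train loss:  "
            f"{self.training_log['train_loss'].iloc[-1]:.4f}",
            f"seed:              {self.seed}",
        ]
        return "\n".join(lines)

    def plot_training(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.training_log["epoch"], self.training_log["train_loss"],
                label="train BCE")
        ax2 = ax.twinx()
        ax2.plot(self.training_log["epoch"], self.training_log["val_auroc"],
                 color="C1", label="val AUROC")
        ax.set_xlabel("epoch")
        ax.set_ylabel("training loss")
        ax2.set_ylabel("validation AUROC")
        return ax


def save_checkpoint(results: "SynergyPredictorResults", outdir) -> None:
    """Checkpoint = weights.npz blob + human-readable JSON sidecar.

    The sidecar records the configuration, entity universes, best epoch,
    seed and training log; the blob stores every network tensor plus the
    entity feature arrays needed for inference.
    """
    import json
    import pathlib
    from dataclasses import asdict

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    arrays = {f"w_{k}": t.data
              for k, t in results.network.named_tensors().items()}
    arrays.update(fpA=results._fpA, prA=results._prA, smA=results._smA)
    np.savez_compressed(out / "weights.npz", **arrays)
    cfg = asdict(results.config)
    cfg["head_widths"] = list(cfg["head_widths"])
    sidecar = {
        "config": cfg,
        "drugs": sorted(results._di, key=results._di.get),
        "samples": sorted(results._si, key=results._si.get),
        "best_epoch": int(results.best_epoch),
        "seed": int(results.seed),
        "training_log": results.training_log.to_dict(orient="list"),
    }
    (out / "sidecar.json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(indir) -> "SynergyPredictorResults":
    """Rebuild an inference-ready Results object from a checkpoint.

    The loaded object predicts and summarizes; it has no triplet table,
    so `evaluate` requires passing triplets through `predict_table`.
    """
    import json
    import pathlib

    indir = pathlib.Path(indir)
    sidecar = json.loads((indir / "sidecar.json").read_text())
    blob = np.load(indir / "weights.npz")
    ccfg = dict(sidecar["config"])
    ccfg["head_widths"] = tuple(ccfg["head_widths"])
    ccfg["pretrain"] = AutoencoderConfig(**ccfg["pretrain"])
    cfg = ModelConfig(**ccfg)
    fpA, prA, smA = blob["fpA"], blob["prA"], blob["smA"]
    net = _Network(cfg, fpA.shape[1], prA.shape[1], smA.shape[1],
                   np.random.default_rng(0))
    for k, t in net.named_tensors().items():
        t.data = blob[f"w_{k}"].copy()
    if cfg.use_dti:   # flat width follows the stored conv geometry
        net.dti_flat = net.dti1[0].data.shape[0]
    di = {d: i for i, d in enumerate(sidecar["drugs"])}
    si = {s: i for i, s in enumerate(sidecar["samples"])}
    return SynergyPredictorResults(
        model=None, network=net, split={"train": [], "val": []},
        sample_stats=None, entity_arrays=(fpA, prA, smA, di, si),
        training_log=pd.DataFrame(sidecar["training_log"]),
        best_epoch=sidecar["best_epoch"], seed=sidecar["seed"])


def train_variant(kind: str, triplets: pd.DataFrame, features: FeatureSet,
                  config: ModelConfig | None = None, split=None,
                  seed: int | None = None) -> SynergyPredictorResults:
    """Train an architectural variant.

    kind = "expression" (the reference model), "mutation" (sample branch
    fed the binary mutation profile) or "ablate_chem" (chemical tokens
    removed; three tokens remain).
    """
    cfg = config or ModelConfig()
    if kind == "expression":
        cfg = cfg.with_(sample_source="expression")
    elif kind == "mutation":
        cfg = cfg.with_(sample_source="mutation")
    elif kind == "ablate_chem":
        cfg = cfg.with_(use_chem=False)
    else:
        raise ValueError(f"unknown variant {kind!r}")
    return SynergyPredictor(triplets, features, cfg).fit(split=split,
                                                         seed=seed)


def ensemble(results, drug_a, drug_b, sample) -> float:
    """Arithmetic-mean probability across trained member models."""
    results = list(results)
    if not results:
        raise ValueError("ensemble requires at least one trained model")
    return float(np.mean([r.predict(drug_a, drug_b, sample)
                          for r in results]))
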