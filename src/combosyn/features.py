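"""Feature engineering for the three predictor branches.

Chemistry: molecular graphs and Morgan fingerprints from SMILES.
Targets: a binary drug x gene interaction matrix diffused over the
protein-protein interaction network by random walk with restart, so a
drug's row reflects pathway context rather than isolated direct targets.
Samples: a marker-gene expression matrix compressed by an autoencoder
pre-trained with input dropout, plus an optional binary mutation profile
restricted to nonsynonymous variant classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rdkit import Chem

from ._autodiff import Adam, Tensor

__all__ = [
    "MolecularGraph", "smiles_to_graph",
    "build_dti_matrix", "propagate",
    "MarkerGeneSet", "select_marker_genes",
    "AutoencoderConfig", "ExpressionEncoder", "pretrain_autoencoder",
    "encode_sample", "mutation_profile", "compress_targets",
    "FeatureSet", "build_features",
]

_ELEMENTS = ["C", "N", "O", "S", "F", "Cl", "Br", "P", "I"]

NONSYNONYMOUS_CLASSES = frozenset({
    "missense", "nonsense", "frameshift_insertion", "frameshift_deletion",
    "splice_site",
})


@dataclass
class MolecularGraph:
    atom_features: np.ndarray   # n_atoms x (|elements|+1 + 3)
    adjacency: np.ndarray       # symmetric binary, zero diagonal
    aromatic: np.ndarray        # per-atom flag (also in atom_features)

    @property
    def n_atoms(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_bonds(self) -> int:
        return int(self.adjacency.sum() // 2)


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Heavy-atom molecular graph: one node per atom, one edge per bond."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    n = mol.GetNumAtoms()
    feats = np.zeros((n, len(_ELEMENTS) + 1 + 3))
    aromatic = np.zeros(n, dtype=bool)
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        sym = atom.GetSymbol()
        k = _ELEMENTS.index(sym) if sym in _ELEMENTS else len(_ELEMENTS)
        feats[i, k] = 1.0
        feats[i, -3] = atom.GetDegree()
        feats[i, -2] = atom.GetFormalCharge()
        feats[i, -1] = float(atom.GetIsAromatic())
        aromatic[i] = atom.GetIsAromatic()
    adj = np.zeros((n, n), dtype=np.uint8)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adj[i, j] = adj[j, i] = 1
    return MolecularGraph(atom_features=feats, adjacency=adj,
                          aromatic=aromatic)


# ------------------------------------------------------------------- DTI

def build_dti_matrix(annotations, universe) -> tuple:
    """Binary drug x gene matrix from (drug, gene) annotation pairs.

    Genes outside `universe` are ignored; the count of ignored
    annotations is returned alongside the matrix.
    """
    universe = list(universe)
    if not universe:
        raise ValueError("target universe must be non-empty")
    gene_pos = {g: i for i, g in enumerate(universe)}
    drugs = sorted({d for d, _ in annotations})
    mat = pd.DataFrame(np.zeros((len(drugs), len(universe))),
                       index=drugs, columns=universe)
    ignored = 0
    for d, g in annotations:
        if g in gene_pos:
            mat.loc[d, g] = 1.0
        else:
            ignored += 1
    if ignored:
        warnings.warn(f"{ignored} annotations referenced genes outside the "
                      "target universe and were ignored")
    return mat, ignored


def _normalized_adjacency(ppi: pd.DataFrame, universe, variant: str):
    nodes = list(universe)
    pos = {g: i for i, g in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    dropped = 0
    for row in ppi.itertuples(index=False):
        a, b, w = row.protein_a, row.protein_b, float(row.weight)
        if a in pos and b in pos:
            A[pos[a], pos[b]] = A[pos[b], pos[a]] = w
        else:
            dropped += 1
    if dropped:
        warnings.warn(f"{dropped} PPI edges touch nodes outside the target "
                      "universe and were dropped")
    keep = np.ones(len(nodes), dtype=bool)
    if variant == "hub_removed":
        deg = (A > 0).sum(axis=1)
        n_remove = int(np.ceil(0.05 * len(nodes)))
        # top degrees, ties broken by node id (earlier id removed first)
        order = sorted(range(len(nodes)), key=lambda i: (-deg[i], nodes[i]))
        keep[order[:n_remove]] = False
        A[~keep, :] = 0.0
        A[:, ~keep] = 0.0
    elif variant == "degree_normalized":
        deg = (A > 0).sum(axis=1).astype(float)
        with np.errstate(divide="ignore"):
            inv = 1.0 / np.sqrt(deg)
        inv[~np.isfinite(inv)] = 0.0
        A = A * inv[:, None] * inv[None, :]
    elif variant != "full":
        raise ValueError(f"unknown propagation variant {variant!r}")
    d = A.sum(axis=1)
    with np.errstate(divide="ignore"):
        dinv = 1.0 / np.sqrt(d)
    dinv[~np.isfinite(dinv)] = 0.0
    S = A * dinv[:, None] * dinv[None, :]
    # isolated nodes keep their own signal: self-loop in the operator,
    # so an edgeless network leaves the input unchanged at any alpha
    iso = d == 0
    S[iso, iso] = 1.0
    return S, keep


def propagate(dti: pd.DataFrame, ppi: pd.DataFrame, alpha: float = 0.5,
              tol: float = 1e-6, variant: str = "full",
              max_iter: int = 10000) -> pd.DataFrame:
    """Random walk with restart of the DTI rows over the PPI network.

    Iterates F <- alpha*F0 + (1-alpha)*S*F with S the symmetrically
    degree-normalized adjacency until the max-abs change drops below
    `tol`.  Variants: "hub_removed" deletes the top-5%-degree nodes
    before normalization; "degree_normalized" additionally down-weights
    edges by 1/sqrt(deg_i*deg_j).
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    S, _ = _normalized_adjacency(ppi, dti.columns, variant)
    F0 = dti.to_numpy(dtype=float).T      # genes x drugs
    F = F0.copy()
    if alpha < 1.0:
        for _ in range(max_iter):
            F_new = alpha * F0 + (1 - alpha) * S @ F
            delta = np.max(np.abs(F_new - F))
            F = F_new
            if delta < tol:
                break
        else:
            raise RuntimeError(
                f"propagation failed to converge (residual {delta:.3g})")
    out = pd.DataFrame(F.T, index=dti.index, columns=dti.columns)
    return out.clip(lower=0.0)


# ----------------------------------------------------------- marker genes

@dataclass
class MarkerGeneSet:
    genes: list
    provenance: dict   # gene -> set of tags in {landmark,variable,hub,target}

    def __len__(self):
        return len(self.genes)


def select_marker_genes(expression: pd.DataFrame, landmark, ppi: pd.DataFrame,
                        dti_universe, variable_frac: float = 0.15,
                        hub_n: int = 1000,
                        score_threshold: float = 0.7) -> MarkerGeneSet:
    """Union of four marker sources with provenance tags.

    (i) the landmark list; (ii) the top `variable_frac` of genes by
    expression variance; (iii) the `hub_n` highest-degree genes in the
    PPI restricted to edges with confidence > `score_threshold` (0-1
    scale); (iv) the drug-target universe.  Deterministic gene order.
    """
    if expression.shape[0] < 2:
        raise ValueError("marker selection requires >= 2 samples")
    prov: dict = {}

    def tag(genes, label):
        for g in genes:
            prov.setdefault(g, set()).add(label)

    tag(landmark, "landmark")
    var = expression.var(axis=0, ddof=1)
    n_var = max(1, int(round(variable_frac * len(var))))
    tag(var.sort_values(ascending=False).index[:n_var], "variable")
    strong = ppi[ppi["weight"] > score_threshold]
    deg = pd.concat([strong["protein_a"], strong["protein_b"]]).value_counts()
    tag(deg.index[:min(hub_n, len(deg))], "hub")
    tag(dti_universe, "target")

    genes = sorted(prov)
    if not genes:
        raise ValueError("marker gene union is empty")
    return MarkerGeneSet(genes=genes, provenance=prov)


# ------------------------------------------------------------ autoencoder

@dataclass
class AutoencoderConfig:
    hidden: int = 96
    bottleneck: int = 32
    dropout: float = 0.2
    lr: float = 1e-3
    epochs: int = 100
    holdout_frac: float = 0.1
    seed: int = 0


@dataclass
class ExpressionEncoder:
    """Pre-trained symmetric autoencoder; the encoder half embeds samples.

    Full-scale runs use widths [G -> 1024 -> 256 -> 1024 -> G]; the desk
    defaults scale the hidden and bottleneck widths down for synthetic
    gene counts.  Per-gene standardization statistics come from the
    encoder's own pre-training rows and are stored here.
    """
    genes: list
    widths: tuple
    weights: list                 # [W1,b1,W2,b2] encoder, [W3,b3,W4,b4] dec
    mean: np.ndarray
    sd: np.ndarray
    dropout: float
    seed: int
    loss_log: pd.DataFrame = field(default_factory=pd.DataFrame)
    best_epoch: int = -1

    @property
    def bottleneck(self) -> int:
        return self.widths[2]

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Deterministic bottleneck embedding (dropout off)."""
        Z = self._standardize(np.atleast_2d(X))
        W1, b1, W2, b2 = self.weights[:4]
        H = np.maximum(Z @ W1 + b1, 0.0)
        return H @ W2 + b2


def _init_linear(rng, n_in, n_out):
    scale = np.sqrt(2.0 / n_in)
    return (Tensor(rng.normal(0, scale, (n_in, n_out)), requires_grad=True),
            Tensor(np.zeros(n_out), requires_grad=True))


def pretrain_autoencoder(expression: pd.DataFrame,
                         cfg: AutoencoderConfig | None = None
                         ) -> ExpressionEncoder:
    """Train the expression autoencoder with input dropout.

    A 10% holdout split is evaluated every epoch; the returned encoder
    carries the weights of the best holdout epoch and the full loss log.
    Expression must already be on the log2(TPM+1) scale.
    """
    cfg = cfg or AutoencoderConfig()
    n, G = expression.shape
    if n < 10:
        raise ValueError("autoencoder pre-training requires >= 10 samples")
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    n_hold = max(1, int(round(cfg.holdout_frac * n)))
    hold_idx, train_idx = perm[:n_hold], perm[n_hold:]
    if len(train_idx) < 1:
        raise ValueError("fewer training samples than required")

    X = expression.to_numpy(dtype=float)
    mean = X[train_idx].mean(axis=0)
    sd = X[train_idx].std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    Ztr, Zho = Z[train_idx], Z[hold_idx]

    widths = (G, cfg.hidden, cfg.bottleneck, cfg.hidden, G)
    params = []
    layers = []
    for a, b in zip(widths[:-1], widths[1:]):
        W, bb = _init_linear(rng, a, b)
        layers.append((W, bb))
        params.extend([W, bb])
    opt = Adam(params, lr=cfg.lr)

    def forward(Zb, drop_mask=None):
        h = Tensor(Zb)
        if drop_mask is not None:
            h = h * Tensor(drop_mask)
        for k, (W, bb) in enumerate(layers):
            h = h @ W + bb
            if k in (0, 2):          # ReLU after first encoder/decoder layer
                h = h.relu()
        return h

    log = []
    best = (np.inf, None, -1)
    for epoch in range(cfg.epochs):
        mask = ((rng.random(Ztr.shape) > cfg.dropout)
                / (1.0 - cfg.dropout)) if cfg.dropout > 0 else None
        opt.zero_grad()
        out = forward(Ztr, mask)
        diff = out - Tensor(Ztr)
        loss = (diff * diff).mean()
        loss.backward()
        opt.step()
        ho = forward(Zho)
        ho_mse = float(((ho.data - Zho) ** 2).mean())
        log.append((epoch, float(loss.data), ho_mse))
        if ho_mse < best[0]:
            best = (ho_mse, [p.data.copy() for p in params], epoch)

    weights = []
    for i in range(0, len(best[1]), 2):
        weights.extend([best[1][i], best[1][i + 1]])
    return ExpressionEncoder(
        genes=list(expression.columns), widths=widths, weights=weights,
        mean=mean, sd=sd, dropout=cfg.dropout, seed=cfg.seed,
        loss_log=pd.DataFrame(log, columns=["epoch", "train_mse",
                                            "holdout_mse"]),
        best_epoch=best[2])


def encode_sample(encoder: ExpressionEncoder, profile) -> np.ndarray:
    """Bottleneck embedding of one sample profile (gene order enforced)."""
    if isinstance(profile, pd.Series):
        if list(profile.index) != encoder.genes:
            missing = [g for g in encoder.genes if g not in profile.index]
            if missing:
                raise ValueError(f"profile is missing encoder genes: "
                                 f"{missing[:5]}...")
            profile = profile.loc[encoder.genes]
        x = profile.to_numpy(dtype=float)
    else:
        x = np.asarray(profile, dtype=float)
        if x.shape[-1] != len(encoder.genes):
            raise ValueError("profile length does not match encoder gene order")
    return encoder.encode(x)[0]


def compress_targets(results, propagated_row) -> np.ndarray:
    """Compressed drug-target embedding via a trained predictor's DTI branch.

    This is the inference face of the predictor's convolutional DTI
    encoder (default 500 intermediate features at full scale).
    """
    return results.compress_targets(propagated_row)


# --------------------------------------------------------------- mutation

def mutation_profile(calls: pd.DataFrame, gene_set) -> pd.DataFrame:
    """Sample x gene binary matrix of nonsynonymous mutation status.

    `calls` has columns sample_id, gene, variant_class.  Only the five
    nonsynonymous classes count; unknown class strings are ignored with
    a warning.
    """
    genes = list(gene_set)
    samples = sorted(calls["sample_id"].unique()) if len(calls) else []
    mat = pd.DataFrame(np.zeros((len(samples), len(genes)), dtype=int),
                       index=samples, columns=genes)
    unknown = 0
    for row in calls.itertuples(index=False):
        cls = str(row.variant_class).lower()
        if cls not in NONSYNONYMOUS_CLASSES:
            if cls not in {"synonymous", "silent"}:
                unknown += 1
            continue
        if row.gene in mat.columns:
            mat.loc[row.sample_id, row.gene] = 1
    if unknown:
        warnings.warn(f"{unknown} calls had unrecognized variant classes and "
                      "were ignored")
    return mat


# ------------------------------------------------------------- FeatureSet

@dataclass
class FeatureSet:
    """All per-entity inputs the predictor needs, keyed by id."""
    fingerprints: pd.DataFrame        # drugs x bits
    dti_binary: pd.DataFrame          # drugs x genes
    dti_propagated: pd.DataFrame      # drugs x genes
    expression: pd.DataFrame          # samples x marker genes (log2 scale)
    mutation: pd.DataFrame | None = None
    marker_genes: MarkerGeneSet | None = None

    @property
    def drugs(self):
        return list(self.fingerprints.index)

    @property
    def samples(self):
        return list(self.expression.index)


def build_features(world, n_bits: int = 2048, alpha: float = 0.5,
                   variant: str = "full") -> FeatureSet:
    """Assemble a FeatureSet from a synthetic world."""
    from .harmonize import morgan_fingerprint

    fps = {}
    for d in world.drugs:
        fps[d] = morgan_fingerprint(world.drug_smiles[d],
                                    n_bits=n_bits).as_array()
    fingerprints = pd.DataFrame.from_dict(fps, orient="index").astype(float)

    annotations = [(d, g) for d in world.drugs for g in world.drug_targets[d]]
    dti, _ = build_dti_matrix(annotations, world.genes)
    prop = propagate(dti, world.ppi_edges, alpha=alpha, variant=variant)

    landmark = [world.genes[p * world.cfg.genes_per_pathway + i]
                for p in range(world.cfg.n_pathways) for i in range(3)]
    target_universe = sorted({g for ts in world.drug_targets.values()
                              for g in ts})
    markers = select_marker_genes(world.expression, landmark,
                                  world.ppi_edges, target_universe,
                                  hub_n=min(1000, len(world.genes)))
    expr = world.expression[markers.genes]
    mut = world.mutation
    return FeatureSet(fingerprints=fingerprints, dti_binary=dti,
                      dti_propagated=prop, expression=expr, mutation=mut,
                      marker_genes=markers)
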