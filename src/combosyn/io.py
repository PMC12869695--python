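"""Readers and writers for the package's plain-text interchange formats."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synergy import DoseResponseBlock

__all__ = [
    "read_smiles", "read_ppi", "read_expression", "read_blocks",
    "write_blocks", "write_triplets", "read_triplets",
]


def read_smiles(path) -> dict:
    """SMILES-per-line file with optional tab-separated id column."""
    out = {}
    with open(path) as fh:
        for k, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0]
            did = parts[1] if len(parts) > 1 else f"drug_{k}"
            out[did] = smiles
    return out


def read_ppi(path) -> pd.DataFrame:
    """PPI edge TSV; combined_score on the 0-1000 STRING convention is
    rescaled to a 0-1 `weight` column."""
    df = pd.read_csv(path, sep="\t")
    if "combined_score" in df.columns and "weight" not in df.columns:
        df["weight"] = df["combined_score"] / 1000.0
    return df[["protein_a", "protein_b", "weight"]]


def read_expression(path) -> pd.DataFrame:
    """Expression TSV (genes x samples) -> samples x genes frame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.T


def write_blocks(blocks, path, viability: bool = False) -> None:
    """Dose-response blocks to long CSV (block_id, drugs, concs, response)."""
    rows = []
    for k, blk in enumerate(blocks):
        for i, ca in enumerate(blk.conc_a):
            for j, cb in enumerate(blk.conc_b):
                r = blk.response[i, j]
                rows.append((k, blk.drug_a, blk.drug_b, blk.sample,
                             ca, cb, 100.0 - r if viability else r))
    pd.DataFrame(rows, columns=["block_id", "drug_row", "drug_col",
                                "sample_id", "conc_r", "conc_c",
                                "response"]).to_csv(path, index=False)


def read_blocks(path, viability: bool = False) -> list:
    """Long CSV -> list of DoseResponseBlock (viability converted to
    % inhibition when requested)."""
    df = pd.read_csv(path)
    blocks = []
    for _, grp in df.groupby("block_id", sort=True):
        conc_a = np.sort(grp["conc_r"].unique())
        conc_b = np.sort(grp["conc_c"].unique())
        mat = (grp.pivot_table(index="conc_r", columns="conc_c",
                               values="response")
               .reindex(index=conc_a, columns=conc_b).to_numpy())
        if viability:
            mat = 100.0 - mat
        blocks.append(DoseResponseBlock(
            drug_a=str(grp["drug_row"].iloc[0]),
            drug_b=str(grp["drug_col"].iloc[0]),
            sample=str(grp["sample_id"].iloc[0]),
            conc_a=conc_a, conc_b=conc_b, response=mat))
    return blocks


def write_triplets(records, path, zip_method: str = "conditional") -> None:
    df = pd.DataFrame(
        [(r.drug_a, r.drug_b, r.sample, r.score_loewe, r.score_bliss,
          r.score_hsa, r.score_zip, r.label) for r in records],
        columns=["drug_a", "drug_b", "sample_id", "score_loewe",
                 "score_bliss", "score_hsa", "score_zip", "label"])
    with open(path, "w") as fh:
        fh.write(f"# zip_method: {zip_method}\n")
        df.to_csv(fh, index=False)


def read_triplets(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
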