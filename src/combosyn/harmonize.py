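"""Drug identity resolution and triplet-table assembly.

Drugs coming from heterogeneous screening sources are matched by exact
structural identity: Morgan fingerprints (radius 2, 2,048 bits) compared
with the Tanimoto index.  Synonyms (Tanimoto = 1.0) are merged onto the
reference id; near matches (>= 0.95) are surfaced in a report for manual
review rather than merged, since structural analogues are not synonyms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

from .synergy import SynergyRecord, average_duplicates, binarize

RDLogger.DisableLog("rdApp.*")

__all__ = ["Fingerprint", "morgan_fingerprint", "tanimoto", "match_drug",
           "assemble_triplets", "AssemblyReport"]

NEAR_MATCH_THRESHOLD = 0.95


@dataclass(frozen=True)
class Fingerprint:
    bits: tuple  # indices of set bits, sorted
    n_bits: int = 2048

    @property
    def n_on(self) -> int:
        return len(self.bits)

    def as_array(self) -> np.ndarray:
        arr = np.zeros(self.n_bits, dtype=np.uint8)
        arr[list(self.bits)] = 1
        return arr


def morgan_fingerprint(smiles: str, radius: int = 2,
                       n_bits: int = 2048) -> Fingerprint:
    """Hashed circular-substructure (Morgan) fingerprint of a molecule."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius,
                                                    fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    return Fingerprint(bits=tuple(fp.GetOnBits()), n_bits=n_bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|intersection| / |union| of set bits; 1.0 for two empty prints."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} != {b.n_bits}")
    sa, sb = set(a.bits), set(b.bits)
    union = len(sa | sb)
    if union == 0:
        return 1.0
    return len(sa & sb) / union


def match_drug(query_smiles: str, reference: dict,
               return_profile: bool = False):
    """Best structural match of a query molecule against a reference library.

    `reference` maps drug id -> Fingerprint.  Returns (best_id,
    similarity, merge) with merge=True iff similarity is exactly 1.0;
    ties at the maximum break to the lexicographically smaller id.  With
    return_profile=True the full similarity profile is appended.
    """
    if not reference:
        raise ValueError("reference library is empty")
    q = morgan_fingerprint(query_smiles)
    profile = {rid: tanimoto(q, fp) for rid, fp in reference.items()}
    best_id = min(profile, key=lambda rid: (-profile[rid], rid))
    sim = profile[best_id]
    merge = sim == 1.0
    if return_profile:
        return best_id, sim, merge, profile
    return best_id, sim, merge


@dataclass
class AssemblyReport:
    n_input: int = 0
    n_output: int = 0
    n_duplicates_merged: int = 0
    n_dropped_drug: int = 0
    n_dropped_sample: int = 0
    merged_synonyms: dict = field(default_factory=dict)   # raw id -> canonical
    near_matches: list = field(default_factory=list)      # (raw, ref, sim)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_output": self.n_output,
            "n_duplicates_merged": self.n_duplicates_merged,
            "n_dropped_drug": self.n_dropped_drug,
            "n_dropped_sample": self.n_dropped_sample,
            "merged_synonyms": self.merged_synonyms,
            "near_matches": [list(t) for t in self.near_matches],
        }


def assemble_triplets(records: pd.DataFrame, drug_library: dict,
                      sample_library) -> tuple:
    """Canonicalize, resolve and de-duplicate a raw triplet table.

    `records` needs columns drug_a, drug_b, sample_id, score_loewe,
    score_bliss, score_hsa, score_zip (missing score columns are filled
    with NaN-free zeros only if absent entirely).  `drug_library` maps
    drug id -> SMILES; ids are resolved against the library's own
    fingerprints so structural synonyms collapse onto one id.  Rows
    whose drugs or samples cannot be resolved are dropped and counted.
    Returns (clean DataFrame, AssemblyReport).
    """
    report = AssemblyReport(n_input=len(records))
    sample_set = set(sample_library)

    fingerprints, failed = {}, set()
    for did, smi in drug_library.items():
        try:
            fingerprints[did] = morgan_fingerprint(smi)
        except ValueError:
            failed.add(did)

    # structural synonym resolution within the library itself: every id
    # maps to the lexicographically smallest id with an identical print
    canonical: dict = {}
    by_bits: dict = {}
    for did in sorted(fingerprints):
        key = fingerprints[did].bits
        if key in by_bits:
            canonical[did] = by_bits[key]
            report.merged_synonyms[did] = by_bits[key]
        else:
            by_bits[key] = did
            canonical[did] = did
    # near matches (non-identical but >= threshold), for manual review
    ids = sorted(by_bits.values())
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            sim = tanimoto(fingerprints[a], fingerprints[b])
            if NEAR_MATCH_THRESHOLD <= sim < 1.0:
                report.near_matches.append((a, b, sim))

    if records.empty:
        report.n_output = 0
        return records.copy(), report

    recs = []
    for row in records.itertuples(index=False):
        a, b, s = row.drug_a, row.drug_b, row.sample_id
        if a not in canonical or b not in canonical or a in failed or b in failed:
            report.n_dropped_drug += 1
            continue
        if s not in sample_set:
            report.n_dropped_sample += 1
            continue
        loewe = float(getattr(row, "score_loewe", 0.0))
        recs.append(SynergyRecord(
            drug_a=canonical[a], drug_b=canonical[b], sample=s,
            score_loewe=loewe,
            score_bliss=float(getattr(row, "score_bliss", 0.0)),
            score_hsa=float(getattr(row, "score_hsa", 0.0)),
            score_zip=float(getattr(row, "score_zip", 0.0)),
            label=binarize(loewe)).canonical())
    merged = average_duplicates(recs)
    report.n_duplicates_merged = len(recs) - len(merged)
    report.n_output = len(merged)
    out = pd.DataFrame(
        [(r.drug_a, r.drug_b, r.sample, r.score_loewe, r.score_bliss,
          r.score_hsa, r.score_zip, r.label) for r in merged],
        columns=["drug_a", "drug_b", "sample_id", "score_loewe",
                 "score_bliss", "score_hsa", "score_zip", "label"])
    return out, report
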