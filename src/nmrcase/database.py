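"""Searchable spectral database: build, two-stage retrieval, persistence.

Every admissible, InChIKey-deduplicated molecule is stored with its
simulated 1H/13C shift multisets and the 256-dimensional encoded vector.
Retrieval runs in two stages: a vector scan by cosine similarity over
L2-normalized encodings selects ``k_ann`` candidates, which are then
re-ranked by the slower but more accurate optimal-assignment set
similarity, returning the top ``k_final``.  The default backend is an
exact brute-force scan (appropriate at desk scale); any approximate
index exposing ``top_k(query_vector, k)`` can be swapped in behind the
same interface.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from . import chem
from .config import SolverConfig, spectral_hash
from .similarity import combined_score
from .spectra import ShiftMultiset, encode_full, simulate_multiset

__all__ = [
    "DBRecord",
    "SpectralDB",
    "RetrievalHit",
    "DBConfigMismatchError",
    "ExactVectorIndex",
    "build_db",
    "retrieve",
    "save_db",
    "load_db",
]

logger = logging.getLogger(__name__)

DB_FORMAT_VERSION = 1


class DBConfigMismatchError(RuntimeError):
    """Stored database was built under a different encoding scheme."""


@dataclass(frozen=True)
class DBRecord:
    smiles: str
    inchikey: str
    formula: str
    h_shifts: tuple[float, ...]
    c_shifts: tuple[float, ...]

    @property
    def h_multiset(self) -> ShiftMultiset:
        return ShiftMultiset("1H", self.h_shifts)

    @property
    def c_multiset(self) -> ShiftMultiset:
        return ShiftMultiset("13C", self.c_shifts)


class ExactVectorIndex:
    """Brute-force cosine scan over L2-normalized vectors (exact)."""

    def __init__(self, vectors: np.ndarray):
        norms = np.linalg.norm(vectors, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        self._unit = vectors / norms

    def top_k(self, query: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Indices and cosine similarities of the k nearest records."""
        qn = np.linalg.norm(query)
        q = query / qn if qn > 0 else query
        sims = self._unit @ q
        k = min(k, len(sims))
        # sort by similarity desc; stable so equal scores keep InChIKey order
        order = np.argsort(-sims, kind="stable")[:k]
        return order, sims[order]


@dataclass
class SpectralDB:
    records: list[DBRecord]
    encodings: np.ndarray  # (n, 2 * n_grid), raw (unnormalized) encodings
    predictor_id: str
    config_hash: str
    index: ExactVectorIndex = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = ExactVectorIndex(self.encodings)

    def __len__(self) -> int:
        return len(self.records)


def build_db(molecules, predictor, config: SolverConfig) -> SpectralDB:
    """Predict, encode and index a molecule collection.

    Inadmissible molecules are dropped with a logged reason, duplicates
    removed by InChIKey, and records sorted by InChIKey so the build is
    independent of input order.
    """
    cfg = config.spectrum
    by_key: dict[str, tuple[DBRecord, np.ndarray]] = {}
    n_dropped = 0
    for mol in molecules:
        smi = chem.canonical_smiles(mol)
        if not chem.admissible(mol):
            logger.info("dropping inadmissible molecule %s", smi)
            n_dropped += 1
            continue
        key = chem.inchikey(mol)
        if key in by_key:
            continue
        h_ms, c_ms = simulate_multiset(mol, predictor)
        vec = encode_full(h_ms, c_ms, cfg)
        by_key[key] = (
            DBRecord(smi, key, chem.molecular_formula(mol),
                     h_ms.shifts, c_ms.shifts),
            vec,
        )
    if not by_key:
        raise ValueError("no admissible molecules; cannot build database")
    keys = sorted(by_key)
    records = [by_key[k][0] for k in keys]
    encodings = np.stack([by_key[k][1] for k in keys])
    logger.info("built database: %d records (%d dropped)", len(records), n_dropped)
    return SpectralDB(records, encodings,
                      predictor_id=predictor.predictor_id,
                      config_hash=spectral_hash(cfg, predictor.predictor_id))


@dataclass(frozen=True)
class RetrievalHit:
    record: DBRecord
    combined: float
    parts: dict[str, float]
    cosine: float

    def to_dict(self) -> dict:
        return {"smiles": self.record.smiles, "inchikey": self.record.inchikey,
                "formula": self.record.formula, "combined": self.combined,
                "parts": self.parts, "cosine": self.cosine}


def retrieve(
    db: SpectralDB,
    query: tuple[ShiftMultiset | None, ShiftMultiset | None],
    config: SolverConfig,
    k_ann: int | None = None,
    k_final: int | None = None,
) -> list[RetrievalHit]:
    """Two-stage retrieval: vector scan, then set-similarity re-rank."""
    k_ann = config.k_ann if k_ann is None else k_ann
    k_final = config.k_final if k_final is None else k_final
    if not (1 <= k_final <= k_ann):
        raise ValueError("need 1 <= k_final <= k_ann")
    h_ms, c_ms = query
    if (h_ms is None or len(h_ms) == 0) and (c_ms is None or len(c_ms) == 0):
        raise ValueError("empty query: no peaks in either nucleus")

    cfg = config.spectrum
    v_query = encode_full(h_ms, c_ms, cfg)
    idx, cosines = db.index.top_k(v_query, k_ann)

    hits: list[RetrievalHit] = []
    for i, cos in zip(idx, cosines):
        rec = db.records[int(i)]
        score, parts = combined_score((h_ms, c_ms),
                                      (rec.h_multiset, rec.c_multiset), cfg)
        hits.append(RetrievalHit(rec, score, parts, float(cos)))
    hits.sort(key=lambda h: (-h.combined, h.record.inchikey))
    return hits[:k_final]


# ---------------------------------------------------------------------------
# persistence: directory with metadata JSON, a records TSV, and a raw
# little-endian float32 vector file

def save_db(db: SpectralDB, path: str) -> None:
    os.makedirs(path, exist_ok=True)
    meta = {
        "format_version": DB_FORMAT_VERSION,
        "n_records": len(db),
        "n_dims": int(db.encodings.shape[1]),
        "predictor_id": db.predictor_id,
        "config_hash": db.config_hash,
    }
    with open(os.path.join(path, "metadata.json"), "w") as fh:
        json.dump(meta, fh, indent=1)
    with open(os.path.join(path, "records.tsv"), "w") as fh:
        fh.write("smiles\tinchikey\tformula\th_shifts\tc_shifts\n")
        for rec in db.records:
            fh.write("\t".join([
                rec.smiles, rec.inchikey, rec.formula,
                ",".join(repr(s) for s in rec.h_shifts),
                ",".join(repr(s) for s in rec.c_shifts),
            ]) + "\n")
    db.encodings.astype("<f4").tofile(os.path.join(path, "vectors.f32"))


def load_db(db_path: str, config: SolverConfig, predictor_id: str) -> SpectralDB:
    """Load a stored database, refusing stale encodings.

    The stored config hash must match the hash of the current spectrum
    configuration + predictor; otherwise the on-disk vectors would not be
    comparable with freshly encoded queries.
    """
    with open(os.path.join(db_path, "metadata.json")) as fh:
        meta = json.load(fh)
    expected = spectral_hash(config.spectrum, predictor_id)
    if meta["config_hash"] != expected:
        raise DBConfigMismatchError(
            f"database at {db_path} was built with config {meta['config_hash']}, "
            f"current configuration hashes to {expected}"
        )
    records: list[DBRecord] = []
    with open(os.path.join(db_path, "records.tsv")) as fh:
        next(fh)
        for line in fh:
            smi, key, formula, h_str, c_str = line.rstrip("\n").split("\t")
            records.append(DBRecord(
                smi, key, formula,
                tuple(float(s) for s in h_str.split(",") if s),
                tuple(float(s) for s in c_str.split(",") if s),
            ))
    vectors = np.fromfile(os.path.join(db_path, "vectors.f32"), dtype="<f4")
    vectors = vectors.reshape(meta["n_records"], meta["n_dims"]).astype(float)
    return SpectralDB(records, vectors, meta["predictor_id"], meta["config_hash"])
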