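"""Molecule and score-table I/O, property filters, and fingerprint featurization.

Reads ``.smi`` files (SMILES, whitespace, identifier per line) and tabular
score files (CSV/TSV with ``id``, ``smiles``, ``score`` columns; scores in
kcal/mol, lower = better), applies the chemical-subspace filters used to
define screening libraries (rule-of-four, lead-like), and turns molecules
into binary Morgan circular fingerprints (the RDKit ECFP analogue).

Molecules that cannot be parsed or featurized are never dropped silently:
every operation returns or records the failures alongside its results.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdFingerprintGenerator

logger = logging.getLogger(__name__)

__all__ = [
    "MoleculeRecord",
    "MoleculeTable",
    "LibraryFilter",
    "FingerprintConfig",
    "FeatureMatrix",
    "read_smiles_table",
    "write_smiles_table",
    "read_score_table",
    "write_score_table",
    "compute_descriptors",
    "apply_library_filter",
    "featurize",
    "write_fingerprint_store",
    "read_fingerprint_store",
]


@dataclass
class MoleculeRecord:
    """One library member: identifier, SMILES, optional computed descriptors."""

    id: str
    smiles: str
    mol_weight: float | None = None
    clogp: float | None = None
    heavy_atom_count: int | None = None

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError(f"record {self.id!r}: empty SMILES")
        if self.heavy_atom_count is not None and self.heavy_atom_count < 1:
            raise ValueError(f"record {self.id!r}: heavy_atom_count must be >= 1")


@dataclass
class MoleculeTable:
    """Parsed molecules plus the rows that failed to parse.

    Iterating the table yields the successfully parsed records; ``failures``
    holds ``(id, smiles, reason)`` triples for the rest.
    """

    records: list[MoleculeRecord]
    failures: list[tuple[str, str, str]] = field(default_factory=list)

    def __iter__(self) -> Iterator[MoleculeRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class LibraryFilter:
    """Property bounds defining a chemical subspace.

    ``max_mw``/``max_clogp`` are strict upper bounds (exclusive); the
    heavy-atom and ``min_clogp`` bounds are inclusive. Unused bounds stay
    ``None``. Use the :meth:`rule_of_four` and :meth:`lead_like` presets for
    the two standard screening subspaces.
    """

    name: str = "custom"
    max_mw: float | None = None
    max_clogp: float | None = None
    min_clogp: float | None = None
    min_hac: int | None = None
    max_hac: int | None = None

    @classmethod
    def rule_of_four(cls) -> "LibraryFilter":
        """MW < 400 Da and cLogP < 4, both strict."""
        return cls(name="rule_of_four", max_mw=400.0, max_clogp=4.0)

    @classmethod
    def lead_like(cls) -> "LibraryFilter":
        """20 <= heavy atoms <= 25 and -5 <= cLogP <= 3.5, all inclusive."""
        return cls(name="lead_like", min_hac=20, max_hac=25,
                   min_clogp=-5.0, max_clogp=3.5)

    def accepts(self, record: MoleculeRecord) -> tuple[bool, str]:
        """Return (kept?, reason). Strictness differs by preset.

        Rule-of-four upper bounds are strict (the subspace is MW < 400 and
        cLogP < 4, so a compound sitting exactly at a bound is rejected);
        lead-like and custom bounds are inclusive.
        """
        strict_upper = self.name == "rule_of_four"
        if self.max_mw is not None:
            mw = record.mol_weight
            if mw is None:
                return False, "missing_mol_weight"
            if (mw >= self.max_mw) if strict_upper else (mw > self.max_mw):
                return False, "mol_weight"
        if self.max_clogp is not None:
            lp = record.clogp
            if lp is None:
                return False, "missing_clogp"
            if (lp >= self.max_clogp) if strict_upper else (lp > self.max_clogp):
                return False, "clogp_high"
        if self.min_clogp is not None:
            lp = record.clogp
            if lp is None:
                return False, "missing_clogp"
            if lp < self.min_clogp:
                return False, "clogp_low"
        if self.min_hac is not None or self.max_hac is not None:
            hac = record.heavy_atom_count
            if hac is None:
                return False, "missing_heavy_atom_count"
            if self.min_hac is not None and hac < self.min_hac:
                return False, "hac_low"
            if self.max_hac is not None and hac > self.max_hac:
                return False, "hac_high"
        return True, ""


@dataclass(frozen=True)
class FingerprintConfig:
    """Morgan fingerprint parameters. radius=2, n_bits=2048 is the
    conventional ECFP4-equivalent setting."""

    radius: int = 2
    n_bits: int = 2048

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        n = self.n_bits
        if n <= 0 or (n & (n - 1)) != 0:
            raise ValueError("n_bits must be a positive power of two")


@dataclass
class FeatureMatrix:
    """Binary feature rows aligned with ``ids``; ``failed_ids`` lists
    molecules that could not be featurized (excluded from ``bits``)."""

    ids: list[str]
    bits: np.ndarray  # (n, n_bits) uint8
    failed_ids: list[str] = field(default_factory=list)
    config: FingerprintConfig | None = None

    def __post_init__(self) -> None:
        if self.bits.ndim != 2 or self.bits.shape[0] != len(self.ids):
            raise ValueError("bits rows must align with ids")
        if set(self.failed_ids) & set(self.ids):
            raise ValueError("failed_ids overlap ids")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = np.asarray(indices)
        return FeatureMatrix(ids=[self.ids[i] for i in idx],
                             bits=self.bits[idx], failed_ids=[],
                             config=self.config)


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "r")


def _parse_mol(smiles: str):
    RDLogger.DisableLog("rdApp.error")
    try:
        return Chem.MolFromSmiles(smiles)
    finally:
        RDLogger.EnableLog("rdApp.error")


def read_smiles_table(path: str | Path, format: str | None = None,
                      validate: bool = True) -> MoleculeTable:
    """Read molecules from a .smi, .csv or .tsv file.

    ``.smi`` dialect: one molecule per line, SMILES then whitespace then
    identifier. CSV/TSV need ``id`` and ``smiles`` columns. Unparseable
    SMILES are routed to ``failures``; input order is preserved. Raises
    ``FileNotFoundError`` for a missing file and ``ValueError`` when a
    non-empty file yields zero parseable rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    rows: list[tuple[str, str]] = []
    if fmt == "smi":
        with _open_text(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                parts = line.split()
                smiles = parts[0]
                mol_id = parts[1] if len(parts) > 1 else f"line_{i + 1}"
                rows.append((mol_id, smiles))
    else:
        sep = "\t" if fmt == "tsv" else ","
        df = pd.read_csv(path, sep=sep, dtype={"id": str, "smiles": str})
        if "id" not in df.columns or "smiles" not in df.columns:
            raise ValueError(f"{path}: expected 'id' and 'smiles' columns")
        rows = list(zip(df["id"], df["smiles"]))

    table = MoleculeTable(records=[])
    for mol_id, smiles in rows:
        if not isinstance(smiles, str) or not smiles:
            table.failures.append((mol_id, str(smiles), "empty_smiles"))
            continue
        if validate and _parse_mol(smiles) is None:
            table.failures.append((mol_id, smiles, "unparseable_smiles"))
            continue
        table.records.append(MoleculeRecord(id=mol_id, smiles=smiles))
    if rows and not table.records:
        raise ValueError(f"{path}: no parseable rows out of {len(rows)}")
    if table.failures:
        logger.warning("%s: %d of %d rows failed to parse",
                       path, len(table.failures), len(rows))
    return table


def _infer_format(path: Path) -> str:
    suffixes = [s.lstrip(".") for s in path.suffixes]
    for s in reversed(suffixes):
        if s in {"smi", "csv", "tsv"}:
            return s
    return "smi"


def write_smiles_table(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    path = Path(path)
    opener = gzip.open(path, "wt") if path.suffix == ".gz" else open(path, "w")
    with opener as fh:
        for rec in records:
            fh.write(f"{rec.smiles} {rec.id}\n")


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Read a score table (CSV/TSV: id, smiles, score[, label])."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if ".tsv" in path.suffixes or path.suffix == ".tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype={"id": str},
                     float_precision="round_trip")
    missing = {"id", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if not np.all(np.isfinite(df["score"].to_numpy(dtype=float))):
        raise ValueError(f"{path}: non-finite scores")
    return df


def write_score_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix == ".tsv" else ","
    # repr-precision floats so a read round-trips scores exactly
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def compute_descriptors(record: MoleculeRecord) -> MoleculeRecord:
    """Return a copy with mol_weight, clogp and heavy_atom_count filled in.

    Raises ``ValueError`` if the SMILES cannot be parsed. The cLogP is the
    RDKit Crippen atom-contribution estimate.
    """
    mol = _parse_mol(record.smiles)
    if mol is None:
        raise ValueError(f"record {record.id!r}: unparseable SMILES")
    return replace(record,
                   mol_weight=Descriptors.MolWt(mol),
                   clogp=Crippen.MolLogP(mol),
                   heavy_atom_count=mol.GetNumHeavyAtoms())


def apply_library_filter(records: Iterable[MoleculeRecord],
                         flt: LibraryFilter,
                         ) -> tuple[list[MoleculeRecord],
                                    list[tuple[MoleculeRecord, str]]]:
    """Partition records into (kept, rejected-with-reason) under a filter.

    Descriptors are computed on demand from SMILES when absent. A record
    whose descriptors cannot be computed is rejected with reason
    ``featurization_failure`` rather than raising mid-stream.
    """
    kept: list[MoleculeRecord] = []
    rejected: list[tuple[MoleculeRecord, str]] = []
    for rec in records:
        needs = ((flt.max_mw is not None and rec.mol_weight is None)
                 or ((flt.max_clogp is not None or flt.min_clogp is not None)
                     and rec.clogp is None)
                 or ((flt.min_hac is not None or flt.max_hac is not None)
                     and rec.heavy_atom_count is None))
        if needs:
            try:
                rec = compute_descriptors(rec)
            except ValueError:
                rejected.append((rec, "featurization_failure"))
                continue
        ok, reason = flt.accepts(rec)
        if ok:
            kept.append(rec)
        else:
            rejected.append((rec, reason))
    return kept, rejected


def featurize(records: Iterable[MoleculeRecord],
              config: FingerprintConfig = FingerprintConfig()) -> FeatureMatrix:
    """Compute binary Morgan fingerprints for a batch of molecules.

    Deterministic for a given (canonical structure, config); equivalent
    SMILES of the same molecule give identical rows. Failures land in
    ``failed_ids``. Raises ``ValueError`` if every molecule fails.
    """
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=config.radius, fpSize=config.n_bits)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    failed: list[str] = []
    n_in = 0
    for rec in records:
        n_in += 1
        mol = _parse_mol(rec.smiles)
        if mol is None:
            failed.append(rec.id)
            continue
        ids.append(rec.id)
        rows.append(gen.GetFingerprintAsNumPy(mol))
    if n_in and not rows:
        raise ValueError("all molecules failed featurization")
    bits = (np.vstack(rows).astype(np.uint8) if rows
            else np.zeros((0, config.n_bits), dtype=np.uint8))
    if failed:
        logger.warning("featurize: %d of %d molecules failed and were excluded",
                       len(failed), n_in)
    return FeatureMatrix(ids=ids, bits=bits, failed_ids=failed, config=config)


def write_fingerprint_store(fm: FeatureMatrix, path: str | Path) -> None:
    """Write fingerprints as 'id<TAB>hex-bitstring' lines (bit-exact)."""
    with open(path, "w") as fh:
        if fm.config is not None:
            fh.write(f"# radius={fm.config.radius} n_bits={fm.config.n_bits}\n")
        for mol_id, row in zip(fm.ids, fm.bits):
            fh.write(f"{mol_id}\t{np.packbits(row).tobytes().hex()}\n")


def read_fingerprint_store(path: str | Path) -> FeatureMatrix:
    ids: list[str] = []
    rows: list[np.ndarray] = []
    config: FingerprintConfig | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                kv = dict(tok.split("=") for tok in line[1:].split())
                config = FingerprintConfig(radius=int(kv["radius"]),
                                           n_bits=int(kv["n_bits"]))
                continue
            mol_id, hexstr = line.split("\t")
            ids.append(mol_id)
            rows.append(np.unpackbits(np.frombuffer(bytes.fromhex(hexstr),
                                                    dtype=np.uint8)))
    bits = np.vstack(rows).astype(np.uint8) if rows else np.zeros((0, 0), np.uint8)
    if config is not None and bits.size:
        bits = bits[:, :config.n_bits]
    return FeatureMatrix(ids=ids, bits=bits, config=config)
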