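"""Scaffold library construction: split, clean, size-filter, validate.

A scaffold library is built from a directory of PDB files. Each entry is
split into single chains, cleaned down to polymer atoms (selenomethionine
rewritten as methionine), filtered to fewer than a configured number of
residues, and sanity-checked for backbone completeness and chain breaks.
Accepted chains are written out one file each, with a TSV manifest and a
JSON parameter sidecar, forming a searchable catalog for motif grafting.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import DEFAULT_CONFIG, RunConfig
from .structure_core import ChainStructure, Residue, parse_pdb, write_pdb

logger = logging.getLogger(__name__)

__all__ = [
    "ScaffoldRecord",
    "CatalogManifest",
    "ValidationReport",
    "NoPolymerError",
    "split_into_chains",
    "clean_chain",
    "size_filter",
    "validate_chain",
    "build_catalog",
    "load_catalog",
]

#: Ions and other single-atom/non-polymer HETATM residues commonly found in
#: crystal structures; removed (with waters and ligands) during cleaning.
_WATER_NAMES = {"HOH", "DOD", "WAT"}


class NoPolymerError(ValueError):
    """A chain contains no polymer residues after cleaning."""


@dataclass
class ScaffoldRecord:
    source_id: str
    residue_count: int
    sequence: str
    validated: bool
    rejection_reason: str = ""
    file_path: str = ""


@dataclass
class CatalogManifest:
    max_residues: int
    cleaning_policy: str
    accepted: int
    rejected: int
    records: list[ScaffoldRecord] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.accepted + self.rejected

    def to_tsv(self) -> str:
        lines = ["source_id\tresidue_count\tsequence\tvalidated\trejection_reason\tfile_path"]
        for r in self.records:
            lines.append(f"{r.source_id}\t{r.residue_count}\t{r.sequence}\t"
                         f"{str(r.validated).lower()}\t{r.rejection_reason}\t{r.file_path}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, max_residues: int = 150,
                 cleaning_policy: str = "") -> "CatalogManifest":
        records = []
        lines = text.strip().splitlines()
        for line in lines[1:]:
            sid, count, seq, valid, reason, path = (line.split("\t") + [""] * 6)[:6]
            records.append(ScaffoldRecord(sid, int(count), seq,
                                          valid == "true", reason, path))
        accepted = sum(r.validated for r in records)
        return cls(max_residues, cleaning_policy, accepted,
                   len(records) - accepted, records)


@dataclass
class ValidationReport:
    source_id: str
    failures: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


# ---------------------------------------------------------------------------
# Pipeline steps
# ---------------------------------------------------------------------------


def split_into_chains(chains: list[ChainStructure]) -> list[ChainStructure]:
    """One independently serializable chain per chain identifier.

    Chains consisting solely of hetero residues (e.g. a chain of waters or a
    free ligand) are dropped with a logged reason.
    """
    kept = []
    for chain in chains:
        if not any(not r.is_hetero or r.name3 == "MSE" for r in chain.residues):
            logger.warning("dropping chain %s: only heteroatom records",
                           chain.source_id)
            continue
        kept.append(chain.copy())
    return kept


def _clean_residue(res: Residue) -> Residue | None:
    if res.name3 in _WATER_NAMES:
        return None
    if res.is_hetero and res.name3 != "MSE":
        return None  # ions, ligands, sugars ...
    out = res.copy()
    out.atoms = [a for a in out.atoms if not a.is_hydrogen]
    for atom in out.atoms:
        atom.from_hetatm = False
    if res.name3 == "MSE":
        out.name3 = "MET"
        for atom in out.atoms:
            if atom.name == "SE":
                atom.name = "SD"
                atom.element = "S"
    return out if out.atoms else None


def clean_chain(chain: ChainStructure) -> ChainStructure:
    """Retain polymer atoms only; rewrite selenomethionine as methionine.

    Waters, ions, ligands and hydrogens are removed. MSE residues (deposited
    as HETATM) are kept, renamed MET, with the SE atom renamed SD and its
    element reassigned to sulfur, so downstream geometry sees a canonical
    chain. Idempotent.
    """
    residues = []
    for res in chain.residues:
        cleaned = _clean_residue(res)
        if cleaned is not None:
            residues.append(cleaned)
    if not residues:
        raise NoPolymerError(f"{chain.source_id}: no polymer")
    return ChainStructure(chain.source_id, chain.chain_id, residues)


def size_filter(chain: ChainStructure,
                max_residues: int = DEFAULT_CONFIG.max_scaffold_size
                ) -> tuple[bool, str]:
    """Accept chains with strictly fewer than ``max_residues`` residues.

    The size is the count of observed residues, not the spread of author
    numbers, so chains with numbering gaps are not over-counted.
    """
    n = chain.length()
    if n < max_residues:
        return True, ""
    return False, f"size: {n} residues >= limit {max_residues}"


def validate_chain(chain: ChainStructure,
                   config: RunConfig = DEFAULT_CONFIG) -> ValidationReport:
    """Sanity-check a cleaned chain for grafting.

    Checks: every residue backbone-complete; standard residue alphabet;
    no consecutive Cα–Cα distance above the chain-break threshold.
    """
    report = ValidationReport(chain.source_id)
    for i, res in enumerate(chain.residues):
        if res.one_letter == "X":
            report.failures.append(f"non-standard residue {res.label}")
        if not res.is_backbone_complete(require_o=(i < chain.length() - 1)):
            report.failures.append(f"incomplete backbone at {res.label}")
    ca = []
    for res in chain.residues:
        atom = res.get_atom("CA")
        ca.append(atom.position if atom is not None else None)
    for i in range(len(ca) - 1):
        if ca[i] is None or ca[i + 1] is None:
            continue
        d = float(np.linalg.norm(ca[i + 1] - ca[i]))
        if d > config.chain_break_distance:
            report.failures.append(
                f"chain break: Cα–Cα {d:.2f} Å between "
                f"{chain.residues[i].label} and {chain.residues[i + 1].label}")
    return report


# ---------------------------------------------------------------------------
# Catalog builder
# ---------------------------------------------------------------------------


def _read_structure_file(path: Path) -> list[ChainStructure]:
    if path.suffix == ".gz":
        text = gzip.open(path, "rt").read()
        stem = Path(path.stem).stem
    else:
        text = path.read_text()
        stem = path.stem
    return parse_pdb(text, entry_id=stem.upper().split("_")[0])


def build_catalog(input_dir: str | Path, output_dir: str | Path,
                  config: RunConfig = DEFAULT_CONFIG) -> CatalogManifest:
    """Run split → clean → size-filter → validate over a directory.

    Writes one PDB per accepted chain into ``output_dir`` plus
    ``manifest.tsv`` and ``parameters.json``. Deterministic: inputs are
    processed in lexicographic order and re-running on identical inputs
    reproduces the manifest byte for byte.
    """
    input_dir = Path(input_dir)
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    policy = "drop waters/ions/ligands/hydrogens; MSE->MET"
    manifest = CatalogManifest(config.max_scaffold_size, policy, 0, 0)

    paths = sorted(p for p in input_dir.iterdir()
                   if p.suffix in (".pdb", ".ent") or p.name.endswith(".pdb.gz"))
    for path in paths:
        try:
            chains = _read_structure_file(path)
        except Exception as exc:  # unreadable file: count, continue
            logger.error("unreadable %s: %s", path.name, exc)
            manifest.records.append(ScaffoldRecord(
                path.stem, 0, "", False, f"unreadable: {exc}"))
            manifest.rejected += 1
            continue
        for chain in split_into_chains(chains):
            record = _process_chain(chain, output_dir, config)
            manifest.records.append(record)
            if record.validated:
                manifest.accepted += 1
            else:
                manifest.rejected += 1

    manifest.records.sort(key=lambda r: r.source_id)
    (output_dir / "manifest.tsv").write_text(manifest.to_tsv())
    (output_dir / "parameters.json").write_text(json.dumps(
        {"max_residues": config.max_scaffold_size, "cleaning_policy": policy,
         "chain_break_distance": config.chain_break_distance},
        indent=2, sort_keys=True) + "\n")
    return manifest


def _process_chain(chain: ChainStructure, output_dir: Path,
                   config: RunConfig) -> ScaffoldRecord:
    try:
        cleaned = clean_chain(chain)
    except NoPolymerError:
        return ScaffoldRecord(chain.source_id, 0, "", False, "no polymer")
    ok, reason = size_filter(cleaned, config.max_scaffold_size)
    if not ok:
        return ScaffoldRecord(chain.source_id, cleaned.length(),
                              cleaned.sequence, False, reason)
    report = validate_chain(cleaned, config)
    if not report.ok:
        return ScaffoldRecord(chain.source_id, cleaned.length(),
                              cleaned.sequence, False,
                              "; ".join(report.failures))
    file_name = f"{cleaned.source_id}.pdb"
    (output_dir / file_name).write_text(write_pdb(cleaned))
    return ScaffoldRecord(cleaned.source_id, cleaned.length(),
                          cleaned.sequence, True, "", file_name)


def load_catalog(catalog_dir: str | Path) -> CatalogManifest:
    """Read a catalog previously written by :func:`build_catalog`."""
    catalog_dir = Path(catalog_dir)
    params = json.loads((catalog_dir / "parameters.json").read_text())
    return CatalogManifest.from_tsv(
        (catalog_dir / "manifest.tsv").read_text(),
        max_residues=params.get("max_residues", 150),
        cleaning_policy=params.get("cleaning_policy", ""))


def load_catalog_chain(catalog_dir: str | Path, record: ScaffoldRecord
                       ) -> ChainStructure:
    path = Path(catalog_dir) / record.file_path
    entry = record.source_id.split("_")[0]
    chains = parse_pdb(path.read_text(), entry_id=entry)
    return chains[0]
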