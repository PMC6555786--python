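"""Chemical-shift I/O: NMR-STAR and tabular readers, atom schemes, profiles.

Reads assigned chemical shifts from NMR-STAR v3.1 (``Atom_chem_shift`` loop)
or v2.1 (``Chem_shift_value`` loop) files, or from a simple TSV dialect with
one row per residue and one column per atom.  Atom selection is governed by
an :class:`AtomScheme` — the fixed, residue-type-specific atom list whose
shifts feed the per-type autoencoder.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, SelectorError

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
STANDARD_AA = tuple(sorted(AA1_TO_3))


def canonical_atom(name: str) -> str:
    """Normalize an atom name: upper-case, ``HN`` -> ``H``."""
    name = name.strip().upper()
    return "H" if name == "HN" else name


def canonical_residue(code: str) -> str | None:
    """Map a residue code (1- or 3-letter, any case) to a one-letter code.

    Returns ``None`` for non-standard residues.
    """
    code = code.strip().upper()
    if len(code) == 1:
        return code if code in AA1_TO_3 else None
    return AA3_TO_1.get(code)


@dataclass
class ShiftRecord:
    """One residue's identity plus its assigned chemical shifts in ppm.

    ``shifts`` maps canonical IUPAC atom names to ppm values; an atom absent
    from the mapping is explicitly missing.
    """

    chain_id: str
    residue_number: int
    residue_type: str
    shifts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.residue_type not in AA1_TO_3:
            raise ParameterError(
                f"residue_type must be a standard one-letter code, "
                f"got {self.residue_type!r}"
            )
        clean: dict[str, float] = {}
        for atom, val in self.shifts.items():
            v = float(val)
            if not math.isfinite(v):
                raise ParameterError(
                    f"non-finite shift for {self.residue_type}"
                    f"{self.residue_number} atom {atom}"
                )
            clean[canonical_atom(atom)] = v
        self.shifts = clean

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_number)


# ---------------------------------------------------------------------------
# Atom schemes
# ---------------------------------------------------------------------------

_BACKBONE = ("N", "C", "CA", "H", "HA")
# Residue types carrying a CB carbon (all but glycine) and those whose HB
# proton is routinely assigned as a single (possibly averaged) resonance.
_HAS_CB = tuple(a for a in STANDARD_AA if a != "G")
_HAS_HB = tuple(a for a in STANDARD_AA if a not in ("G", "T", "V", "I"))


@dataclass(frozen=True)
class AtomScheme:
    """A named, residue-type-specific ordered atom list.

    The order is fixed and identical between training and inference; the
    model input layout for a residue type is exactly ``atoms_for[type]``.
    """

    name: str
    atoms_for: Mapping[str, tuple[str, ...]]

    def atoms(self, residue_type: str) -> tuple[str, ...]:
        try:
            return self.atoms_for[residue_type]
        except KeyError:
            raise ParameterError(
                f"scheme {self.name!r} does not cover residue type "
                f"{residue_type!r}"
            ) from None

    @property
    def all_atoms(self) -> frozenset[str]:
        return frozenset(a for atoms in self.atoms_for.values() for a in atoms)


def common_scheme() -> AtomScheme:
    """N, C, CA, CB, H, HA — minus CB for glycine, minus H for proline."""
    atoms_for = {}
    for aa in STANDARD_AA:
        atoms = ["N", "C", "CA", "CB", "H", "HA"]
        if aa == "G":
            atoms.remove("CB")
        if aa == "P":
            atoms.remove("H")
        atoms_for[aa] = tuple(atoms)
    return AtomScheme("common", atoms_for)


def minimal_scheme(carbonyl: bool = False) -> AtomScheme:
    """N, H, CA — minus H for proline.

    ``carbonyl=True`` substitutes the carbonyl C for CA (the variant used in
    free/bound dimer comparisons where CA assignments are sparse).
    """
    third = "C" if carbonyl else "CA"
    atoms_for = {}
    for aa in STANDARD_AA:
        atoms = ["N", "H", third]
        if aa == "P":
            atoms.remove("H")
        atoms_for[aa] = tuple(atoms)
    return AtomScheme("minimal_c" if carbonyl else "minimal", atoms_for)


def full_scheme(
    overrides: Mapping[str, Sequence[str]] | None = None,
) -> AtomScheme:
    """Backbone N, C, CA, H, HA plus CB and HB where chemically present.

    The shipped per-type lists are a documented approximation chosen for
    data abundance; ``overrides`` replaces the list for any residue type.
    """
    atoms_for: dict[str, tuple[str, ...]] = {}
    for aa in STANDARD_AA:
        atoms = list(_BACKBONE)
        if aa == "P":
            atoms.remove("H")
        if aa in _HAS_CB:
            atoms.insert(2, "CB")
        if aa in _HAS_HB:
            atoms.append("HB")
        atoms_for[aa] = tuple(atoms)
    if overrides:
        for aa, atoms in overrides.items():
            code = canonical_residue(aa)
            if code is None:
                raise ParameterError(f"unknown residue type {aa!r} in overrides")
            atoms_for[code] = tuple(canonical_atom(a) for a in atoms)
    return AtomScheme("full", atoms_for)


def get_scheme(name: str) -> AtomScheme:
    """Look up a scheme by name: full, common, minimal or minimal_c."""
    builders = {
        "full": full_scheme,
        "common": common_scheme,
        "minimal": minimal_scheme,
        "minimal_c": lambda: minimal_scheme(carbonyl=True),
    }
    try:
        return builders[name]()
    except KeyError:
        raise ParameterError(
            f"unknown scheme {name!r}; choose from {sorted(builders)}"
        ) from None


#: Atoms retained at parse time (union over all shipped schemes).
KNOWN_ATOMS = frozenset().union(
    full_scheme().all_atoms, common_scheme().all_atoms, minimal_scheme().all_atoms
)


@dataclass
class ProteinShiftTable:
    """An ordered collection of :class:`ShiftRecord` for one entry.

    Records are kept sorted by (chain_id, residue_number) and keys are
    unique.
    """

    entry_id: str
    records: list[ShiftRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: r.key)
        keys = [r.key for r in self.records]
        if len(set(keys)) != len(keys):
            raise ParameterError(f"duplicate (chain, residue) keys in {self.entry_id}")

    @property
    def sequence(self) -> str:
        return "".join(r.residue_type for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ShiftRecord]:
        return iter(self.records)


@dataclass
class ProfileEntry:
    chain_id: str
    residue_number: int
    residue_type: str
    index: float | None
    status: str  # ok | missing_atoms | unsupported_type


@dataclass
class ShiftCryptProfile:
    """Ordered per-residue index values in (0,1), aligned to a sequence."""

    entry_id: str
    entries: list[ProfileEntry] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(e.residue_type for e in self.entries)

    @property
    def values(self) -> np.ndarray:
        """Index values as a float array with NaN for missing."""
        return np.array(
            [np.nan if e.index is None else e.index for e in self.entries]
        )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ProfileEntry]:
        return iter(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ShiftCryptProfile):
            return NotImplemented
        if self.entry_id != other.entry_id or len(self) != len(other):
            return False
        for a, b in zip(self.entries, other.entries):
            if (a.chain_id, a.residue_number, a.residue_type, a.status) != (
                b.chain_id, b.residue_number, b.residue_type, b.status
            ):
                return False
            if (a.index is None) != (b.index is None):
                return False
            if a.index is not None and abs(a.index - b.index) > 1e-9:
                return False
        return True


# ---------------------------------------------------------------------------
# NMR-STAR parsing
# ---------------------------------------------------------------------------

def _tokenize_star(text: str) -> Iterator[str]:
    """Yield STAR tokens: bare words, quoted strings, semicolon blocks."""
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith(";"):  # multi-line text block
            i += 1
            while i < len(lines) and not lines[i].startswith(";"):
                i += 1
            i += 1
            yield ""
            continue
        pos = 0
        n = len(line)
        while pos < n:
            ch = line[pos]
            if ch.isspace():
                pos += 1
                continue
            if ch == "#":
                break
            if ch in "'\"":
                end = line.find(ch, pos + 1)
                # quote not closed on this line: treat as bare token
                if end == -1:
                    yield line[pos:]
                    break
                yield line[pos + 1 : end]
                pos = end + 1
                continue
            end = pos
            while end < n and not line[end].isspace():
                end += 1
            yield line[pos:end]
            pos = end
        i += 1


_V3_TAGS = {
    "seq": ("_atom_chem_shift.comp_index_id", "_atom_chem_shift.seq_id"),
    "comp": ("_atom_chem_shift.comp_id",),
    "atom": ("_atom_chem_shift.atom_id",),
    "val": ("_atom_chem_shift.val",),
    "chain": ("_atom_chem_shift.entity_assembly_id", "_atom_chem_shift.entity_id"),
    "auth_seq": ("_atom_chem_shift.auth_seq_id",),
}
_V2_TAGS = {
    "seq": ("_residue_seq_code",),
    "comp": ("_residue_label",),
    "atom": ("_atom_name",),
    "val": ("_chem_shift_value",),
    "chain": ("_mol_system_component_name",),
    "auth_seq": (),
}


def _find_shift_loops(tokens: list[str]) -> list[tuple[list[str], list[str]]]:
    """Return (tags, values) for every assigned-chemical-shift loop."""
    loops = []
    i = 0
    while i < len(tokens):
        if tokens[i].lower() != "loop_":
            i += 1
            continue
        i += 1
        tags: list[str] = []
        while i < len(tokens) and tokens[i].startswith("_"):
            tags.append(tokens[i])
            i += 1
        values: list[str] = []
        while i < len(tokens):
            tok = tokens[i]
            low = tok.lower()
            if low in ("stop_", "loop_") or low.startswith("save_"):
                break
            values.append(tok)
            i += 1
        lower = [t.lower() for t in tags]
        if any(t in lower for t in ("_atom_chem_shift.val", "_chem_shift_value")):
            loops.append((lower, values))
    return loops


def parse_star(
    path: str | Path, entity_selector: str | None = None
) -> ProteinShiftTable:
    """Read assigned chemical shifts from an NMR-STAR v3.1 or v2.1 file.

    Parameters
    ----------
    path:
        File containing at least one ``Atom_chem_shift`` (v3.1) or
        ``Chem_shift_value`` (v2.1) loop.
    entity_selector:
        Restrict to one entity/assembly (value of the chain column).  With
        ``None`` all entities are read.

    Returns
    -------
    ProteinShiftTable
        One record per (chain, residue) with all assigned shifts for atoms
        known to any scheme; other atoms and ambiguity codes are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    tokens = list(_tokenize_star(path.read_text()))
    loops = _find_shift_loops(tokens)
    if not loops:
        raise FormatError(f"no assigned-chemical-shift loop found in {path}")

    records: dict[tuple[str, int], ShiftRecord] = {}
    seen_entities: set[str] = set()
    warned_types: set[str] = set()
    for tags, values in loops:
        v3 = "_atom_chem_shift.val" in tags
        tagmap = _V3_TAGS if v3 else _V2_TAGS

        def col(role: str) -> int | None:
            for cand in tagmap[role]:
                if cand in tags:
                    return tags.index(cand)
            return None

        c_seq, c_comp, c_atom, c_val = (col(r) for r in ("seq", "comp", "atom", "val"))
        if None in (c_seq, c_comp, c_atom, c_val):
            raise FormatError(
                f"shift loop in {path} lacks residue/atom/value columns"
            )
        c_chain = col("chain")
        ncol = len(tags)
        if ncol == 0 or len(values) % ncol != 0:
            raise FormatError(f"ragged shift loop in {path}")
        for row_start in range(0, len(values), ncol):
            row = values[row_start : row_start + ncol]
            chain = row[c_chain] if c_chain is not None else "1"
            if chain in (".", "?", ""):
                chain = "1"
            seen_entities.add(chain)
            if entity_selector is not None and chain != entity_selector:
                continue
            raw_val = row[c_val]
            if raw_val in (".", "?", ""):
                continue
            comp = canonical_residue(row[c_comp])
            if comp is None:
                if row[c_comp] not in warned_types:
                    warned_types.add(row[c_comp])
                    warnings.warn(
                        f"skipping non-standard residue type {row[c_comp]!r} "
                        f"in {path.name}",
                        stacklevel=2,
                    )
                continue
            atom = canonical_atom(row[c_atom])
            if atom not in KNOWN_ATOMS:
                continue
            try:
                seq = int(row[c_seq])
                val = float(raw_val)
            except ValueError as exc:
                raise FormatError(
                    f"bad row in shift loop of {path}: {row!r}"
                ) from exc
            key = (chain, seq)
            rec = records.get(key)
            if rec is None:
                rec = ShiftRecord(chain, seq, comp)
                records[key] = rec
            if atom in rec.shifts:
                warnings.warn(
                    f"duplicate shift for {chain}:{seq}:{atom} in "
                    f"{path.name}; keeping first",
                    stacklevel=2,
                )
                continue
            rec.shifts[atom] = val

    if entity_selector is not None and not records:
        raise SelectorError(
            f"entity {entity_selector!r} not found in {path}; "
            f"available: {sorted(seen_entities)}"
        )
    return ProteinShiftTable(path.stem, list(records.values()))


# ---------------------------------------------------------------------------
# Tabular dialect
# ---------------------------------------------------------------------------

def parse_table(path: str | Path) -> ProteinShiftTable:
    """Read the TSV dialect: chain, residue_number, residue_type, atom columns."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chain": str})
    except Exception as exc:  # pragma: no cover - pandas error passthrough
        raise FormatError(f"cannot read table {path}: {exc}") from exc
    required = {"chain", "residue_number", "residue_type"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"table {path} lacks required columns {sorted(required)}"
        )
    atom_cols = [c for c in df.columns if c not in required]
    records = []
    for _, row in df.iterrows():
        rtype = canonical_residue(str(row["residue_type"]))
        if rtype is None:
            warnings.warn(
                f"skipping non-standard residue type {row['residue_type']!r}",
                stacklevel=2,
            )
            continue
        shifts = {
            canonical_atom(c): float(row[c])
            for c in atom_cols
            if pd.notna(row[c])
        }
        records.append(
            ShiftRecord(str(row["chain"]), int(row["residue_number"]), rtype, shifts)
        )
    return ProteinShiftTable(path.stem, records)


def write_table(table: ProteinShiftTable, path: str | Path) -> None:
    """Write a shift table in the TSV dialect (empty cell = missing)."""
    atom_cols = sorted({a for r in table for a in r.shifts})
    rows = []
    for r in table:
        row = {
            "chain": r.chain_id,
            "residue_number": r.residue_number,
            "residue_type": r.residue_type,
        }
        row.update({a: r.shifts.get(a) for a in atom_cols})
        rows.append(row)
    cols = ["chain", "residue_number", "residue_type", *atom_cols]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_star(table: ProteinShiftTable, path: str | Path) -> None:
    """Write a minimal NMR-STAR v3.1 file with one Atom_chem_shift loop."""
    lines = [
        f"data_{table.entry_id}",
        "",
        "save_assigned_chemical_shifts",
        "   _Assigned_chem_shift_list.Sf_category   assigned_chemical_shifts",
        "   loop_",
        "      _Atom_chem_shift.ID",
        "      _Atom_chem_shift.Entity_assembly_ID",
        "      _Atom_chem_shift.Comp_index_ID",
        "      _Atom_chem_shift.Comp_ID",
        "      _Atom_chem_shift.Atom_ID",
        "      _Atom_chem_shift.Val",
        "",
    ]
    i = 1
    for rec in table:
        for atom in sorted(rec.shifts):
            lines.append(
                f"      {i} {rec.chain_id} {rec.residue_number} "
                f"{AA1_TO_3[rec.residue_type]} {atom} {rec.shifts[atom]:.3f}"
            )
            i += 1
    lines += ["   stop_", "save_", ""]
    Path(path).write_text("\n".join(lines))


def select_atoms(
    record: ShiftRecord, scheme: AtomScheme
) -> tuple[np.ndarray, np.ndarray]:
    """Extract a record's shifts in scheme order.

    Returns ``(values, missing)``: a float vector of length equal to the
    scheme's atom list for the record's residue type (NaN in missing slots)
    and a boolean mask that is True where the atom is absent.
    """
    atoms = scheme.atoms(record.residue_type)
    values = np.array([record.shifts.get(a, np.nan) for a in atoms])
    return values, np.isnan(values)


# ---------------------------------------------------------------------------
# Profile serialization
# ---------------------------------------------------------------------------

_PROFILE_COLS = ("chain", "residue_number", "residue_type", "shiftcrypt", "status")


def write_profile(
    profile: ShiftCryptProfile, path: str | Path, format: str = "tsv"
) -> None:
    """Write a profile as TSV (missing index -> ``NA``) or JSON."""
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(_PROFILE_COLS) + "\n")
            for e in profile:
                idx = "NA" if e.index is None else f"{e.index:.6f}"
                fh.write(
                    f"{e.chain_id}\t{e.residue_number}\t{e.residue_type}"
                    f"\t{idx}\t{e.status}\n"
                )
    elif format == "json":
        payload = {
            "entry_id": profile.entry_id,
            "entries": [
                {
                    "chain": e.chain_id,
                    "residue_number": e.residue_number,
                    "residue_type": e.residue_type,
                    "shiftcrypt": e.index,
                    "status": e.status,
                }
                for e in profile
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ParameterError(f"unknown profile format {format!r}")


def read_profile(path: str | Path) -> ShiftCryptProfile:
    """Read a profile written by :func:`write_profile` (TSV or JSON)."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("{"):
        payload = json.loads(text)
        entries = [
            ProfileEntry(
                str(e["chain"]), int(e["residue_number"]), e["residue_type"],
                e["shiftcrypt"], e["status"],
            )
            for e in payload["entries"]
        ]
        return ShiftCryptProfile(payload["entry_id"], entries)
    lines = text.splitlines()
    if not lines or lines[0].split("\t") != list(_PROFILE_COLS):
        raise FormatError(f"{path} is not a shiftcodec profile")
    entries = []
    for line in lines[1:]:
        if not line.strip():
            continue
        chain, num, rtype, idx, status = line.split("\t")
        entries.append(
            ProfileEntry(
                chain, int(num), rtype,
                None if idx == "NA" else float(idx), status,
            )
        )
    return ShiftCryptProfile(path.stem, entries)


def records_by_position(
    table: ProteinShiftTable,
) -> list[ShiftRecord]:
    """Records in profile order (sorted by chain, residue number)."""
    return list(table.records)


def iter_scheme_vectors(
    tables: Iterable[ProteinShiftTable], scheme: AtomScheme
) -> Iterator[tuple[ShiftRecord, np.ndarray, np.ndarray]]:
    """Yield (record, values, missing-mask) for every residue of a pool."""
    for table in tables:
        for rec in table:
            vals, mask = select_atoms(rec, scheme)
            yield rec, vals, mask
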