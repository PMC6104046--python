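"""Morphological and molecular character data: reading, validation, recoding.

The data model follows standard total-evidence practice: a discrete
morphological matrix (with ordered characters, polymorphic cells,
missing ``?`` and inapplicable ``-`` observations), a partitioned
molecular supermatrix, and per-taxon metadata (extant flag,
stratigraphic age window in Ma, biogeographic area).  The three are
combined into a :class:`CombinedDataset`, the unit every inference
stage consumes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing observation ("?")
MISSING = "?"
#: sentinel for an inapplicable observation ("-"); treated like missing
#: in the likelihood, but preserved verbatim on round-trip
INAPPLICABLE = "-"

AREAS = (
    "North America",
    "South America",
    "Europe",
    "Asia",
    "Afro-Arabia",
    "Madagascar",
)

#: ordered transformation series longer than this are left with
#: standard polymorphic scoring (the common six-state tool limit)
MAX_ORDERED_STATES = 6


class CharacterDataError(ValueError):
    """Raised on malformed or inconsistent character data."""


@dataclass(frozen=True)
class TaxonRecord:
    """Metadata for one taxon.

    ``age_window`` is the stratigraphic interval ``(min_Ma, max_Ma)``
    within which a fossil tip's age is sampled; extant taxa have
    ``(0, 0)``.  ``area`` is one of the six land masses, or ``None``
    when biogeography is not being analysed.
    """

    name: str
    extant: bool
    age_window: tuple[float, float] = (0.0, 0.0)
    area: str | None = None

    def __post_init__(self):
        lo, hi = self.age_window
        if lo > hi:
            raise CharacterDataError(
                f"{self.name}: age window min {lo} > max {hi}")
        if lo < 0:
            raise CharacterDataError(f"{self.name}: negative age {lo}")
        if self.extant and (lo, hi) != (0.0, 0.0):
            raise CharacterDataError(
                f"{self.name}: extant taxon must have age window [0, 0]")
        if self.area is not None and self.area not in AREAS:
            raise CharacterDataError(
                f"{self.name}: unknown area {self.area!r}; "
                f"expected one of {AREAS}")

    @property
    def midpoint_age(self) -> float:
        return 0.5 * (self.age_window[0] + self.age_window[1])


def normalize_name(name: str) -> str:
    """Exact matching after whitespace/underscore normalization."""
    return "_".join(name.strip().split()).replace(" ", "_")


# ---------------------------------------------------------------------------
# Morphological matrix


Cell = object  # frozenset of state ints, MISSING, or INAPPLICABLE


@dataclass
class MorphMatrix:
    """Discrete morphological character matrix.

    ``cells[i][j]`` is the observation of character *j* in taxon *i*:
    a ``frozenset`` of state indices (singleton for an unambiguous
    observation, larger for a polymorphism), or one of the sentinels
    :data:`MISSING` / :data:`INAPPLICABLE`.
    """

    taxa: list[str]
    cells: list[list[Cell]]
    n_states: np.ndarray          # declared state count per character
    ordered: np.ndarray           # bool per character
    recoded_flags: np.ndarray = None   # chars left with polymorphic scoring
    _recode_done: np.ndarray = None    # internal: recoding already applied

    def __post_init__(self):
        self.n_states = np.asarray(self.n_states, dtype=int)
        self.ordered = np.asarray(self.ordered, dtype=bool)
        if self.recoded_flags is None:
            self.recoded_flags = np.zeros(self.n_chars, dtype=bool)
        if self._recode_done is None:
            self._recode_done = np.zeros(self.n_chars, dtype=bool)
        self.validate()

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return len(self.n_states)

    def validate(self) -> None:
        if len(self.cells) != self.n_taxa:
            raise CharacterDataError(
                f"{len(self.cells)} rows for {self.n_taxa} taxa")
        for i, row in enumerate(self.cells):
            if len(row) != self.n_chars:
                raise CharacterDataError(
                    f"row {i} has {len(row)} cells, expected {self.n_chars}")
            for j, cell in enumerate(row):
                if cell in (MISSING, INAPPLICABLE):
                    continue
                if not cell or max(cell) >= self.n_states[j]:
                    raise CharacterDataError(
                        f"taxon {self.taxa[i]!r} char {j}: state set "
                        f"{set(cell)} exceeds declared count "
                        f"{self.n_states[j]}")
        if int(self.recoded_flags.sum()) > int(self.ordered.sum()):
            raise CharacterDataError(
                "more recoded characters than ordered characters")

    def column(self, j: int) -> list[Cell]:
        return [row[j] for row in self.cells]

    def cell_count(self) -> int:
        """Number of non-missing observations (for accounting checks)."""
        return sum(
            1 for row in self.cells for c in row
            if c not in (MISSING, INAPPLICABLE))

    def copy(self) -> "MorphMatrix":
        return MorphMatrix(
            taxa=list(self.taxa),
            cells=[list(r) for r in self.cells],
            n_states=self.n_states.copy(),
            ordered=self.ordered.copy(),
            recoded_flags=self.recoded_flags.copy(),
            _recode_done=self._recode_done.copy(),
        )

    def __eq__(self, other):
        if not isinstance(other, MorphMatrix):
            return NotImplemented
        return (self.taxa == other.taxa
                and self.cells == other.cells
                and np.array_equal(self.n_states, other.n_states)
                and np.array_equal(self.ordered, other.ordered)
                and np.array_equal(self.recoded_flags, other.recoded_flags))


_SYMBOLS = "0123456789"


def _cell_to_symbol(cell: Cell) -> str:
    if cell is MISSING or cell == MISSING:
        return MISSING
    if cell is INAPPLICABLE or cell == INAPPLICABLE:
        return INAPPLICABLE
    states = sorted(cell)
    if len(states) == 1:
        return _SYMBOLS[states[0]]
    return "(" + "".join(_SYMBOLS[s] for s in states) + ")"


def write_morph_nexus(m: MorphMatrix, path, sidecar_path=None) -> None:
    """Write a standard-data NEXUS file plus an ordering sidecar JSON."""
    max_state = int(m.n_states.max()) if m.n_chars else 1
    symbols = _SYMBOLS[:max(max_state, 1)]
    width = max(len(t) for t in m.taxa) + 2
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"DIMENSIONS NTAX={m.n_taxa} NCHAR={m.n_chars};\n")
        fh.write(f'FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" '
                 "MISSING=? GAP=-;\nMATRIX\n")
        for taxon, row in zip(m.taxa, m.cells):
            seq = "".join(_cell_to_symbol(c) for c in row)
            fh.write(f"{taxon:<{width}}{seq}\n")
        fh.write(";\nEND;\n")
    if sidecar_path is not None:
        write_ordering_sidecar(m, sidecar_path)


def write_ordering_sidecar(m: MorphMatrix, path) -> None:
    payload = {
        "n_chars": m.n_chars,
        "ordered": [int(j) for j in np.flatnonzero(m.ordered)],
        "n_states": [int(k) for k in m.n_states],
        "recoded": [int(j) for j in np.flatnonzero(m.recoded_flags)],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_morph_nexus(path, sidecar=None) -> MorphMatrix:
    """Read a morphological NEXUS matrix.

    ``sidecar`` (path or dict) supplies per-character ordering flags and
    declared state counts; it is authoritative over anything inferred
    from the matrix.  Without it every character is unordered with state
    count = max observed state + 1.
    """
    try:
        dmat = dendropy.StandardCharacterMatrix.get(
            path=str(path), schema="nexus")
    except Exception as exc:  # dendropy raises several parse error types
        raise CharacterDataError(f"NEXUS parse error in {path}: {exc}") from exc

    taxa: list[str] = []
    cells: list[list[Cell]] = []
    for taxon in dmat:
        taxa.append(normalize_name(taxon.label))
        row: list[Cell] = []
        for st in dmat[taxon]:
            sym = st.symbol
            if sym == "?":
                row.append(MISSING)
            elif sym == "-":
                row.append(INAPPLICABLE)
            elif st.state_denomination == 0:
                if sym not in _SYMBOLS:
                    raise CharacterDataError(
                        f"undeclared symbol {sym!r} in {path}")
                row.append(frozenset([int(sym)]))
            else:
                members = [s.symbol for s in st.member_states
                           if s.symbol not in ("?", "-")]
                row.append(frozenset(int(s) for s in members))
        cells.append(row)
    if not cells:
        raise CharacterDataError(f"no data rows in {path}")

    n_chars = len(cells[0])
    max_obs = np.zeros(n_chars, dtype=int)
    for row in cells:
        for j, c in enumerate(row):
            if c not in (MISSING, INAPPLICABLE):
                max_obs[j] = max(max_obs[j], max(c))
    n_states = max_obs + 1
    n_states = np.maximum(n_states, 2)
    ordered = np.zeros(n_chars, dtype=bool)
    recoded = np.zeros(n_chars, dtype=bool)

    if sidecar is not None:
        cfg = sidecar
        if not isinstance(sidecar, dict):
            with open(sidecar) as fh:
                cfg = json.load(fh)
        if cfg.get("n_chars", n_chars) != n_chars:
            raise CharacterDataError(
                f"sidecar declares {cfg['n_chars']} characters, matrix has "
                f"{n_chars}")
        for j in cfg.get("ordered", []):
            ordered[j] = True
        if "n_states" in cfg:
            declared = np.asarray(cfg["n_states"], dtype=int)
            if np.any(declared < n_states):
                bad = int(np.flatnonzero(declared < n_states)[0])
                raise CharacterDataError(
                    f"char {bad}: observed states exceed sidecar state count")
            n_states = declared
        for j in cfg.get("recoded", []):
            recoded[j] = True

    m = MorphMatrix(taxa=taxa, cells=cells, n_states=n_states,
                    ordered=ordered, recoded_flags=recoded)
    logger.info("read %s: %d taxa x %d characters (%d ordered)",
                path, m.n_taxa, m.n_chars, int(ordered.sum()))
    return m


# ---------------------------------------------------------------------------
# Ordered-polymorphism recoding


def _recode_one_character(column, k, policy):
    """Recode one ordered character column; returns (new_column, new_k,
    left_polymorphic_flag)."""
    poly = [c for c in column
            if c not in (MISSING, INAPPLICABLE) and len(c) > 1]
    if not poly:
        return column, k, False

    for cell in poly:
        states = sorted(cell)
        contiguous = states == list(range(states[0], states[-1] + 1))
        if not contiguous:
            if policy == "reject":
                raise CharacterDataError(
                    f"polymorphism {set(cell)} spans non-adjacent ordered "
                    "states")
            logger.warning(
                "polymorphism %s spans non-adjacent ordered states; "
                "character left with polymorphic scoring", set(cell))
            return column, k, True

    # adjacent original pairs that co-occur inside some polymorphism
    pairs = sorted({(a, a + 1) for cell in poly
                    for a in range(min(cell), max(cell))})
    new_k = k + len(pairs)
    if new_k > MAX_ORDERED_STATES:
        logger.info(
            "recoding would need %d states (> %d); using standard "
            "polymorphic scoring", new_k, MAX_ORDERED_STATES)
        return column, k, True

    # old state s -> new label s + number of inserted intermediates below s
    def relabel(s):
        return s + sum(1 for a, _ in pairs if a < s)

    new_col = []
    for c in column:
        if c in (MISSING, INAPPLICABLE):
            new_col.append(c)
        elif len(c) == 1:
            new_col.append(frozenset([relabel(next(iter(c)))]))
        else:
            lo, hi = relabel(min(c)), relabel(max(c))
            # interior new labels between the endpoints; an adjacent pair
            # collapses to its single inserted intermediate
            new_col.append(frozenset(range(lo + 1, hi)))
    return new_col, new_k, False


def recode_ordered_polymorphisms(m: MorphMatrix,
                                 policy: str = "leave") -> MorphMatrix:
    """Insert intermediate states for polymorphic cells of ordered characters.

    For each ordered character, every adjacent pair of original states
    that co-occurs in a polymorphic cell gains an inserted intermediate
    state; states are relabeled once at the end to keep a contiguous
    ordered scale, and a polymorphic pair ``{a, a+1}`` becomes the single
    intermediate.  A character whose expanded scale would exceed
    :data:`MAX_ORDERED_STATES` keeps standard polymorphic scoring and has
    its ``recoded_flag`` set.  ``policy`` ("leave" or "reject") governs
    polymorphisms spanning non-adjacent ordered states.  Idempotent.
    """
    if policy not in ("leave", "reject"):
        raise ValueError(f"unknown policy {policy!r}")
    out = m.copy()
    for j in range(m.n_chars):
        if not m.ordered[j] or m._recode_done[j] or m.recoded_flags[j]:
            continue
        col, new_k, left_poly = _recode_one_character(
            m.column(j), int(m.n_states[j]), policy)
        for i in range(m.n_taxa):
            out.cells[i][j] = col[i]
        out.n_states[j] = new_k
        out.recoded_flags[j] = left_poly
        out._recode_done[j] = True
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Molecular supermatrix

_NUC = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


@dataclass
class MolecularSupermatrix:
    """Concatenated nucleotide alignment with a partition scheme.

    ``sites`` holds integer-coded bases (A,C,G,T = 0..3; anything
    ambiguous or missing = 4).  ``segment_map`` assigns half-open site
    ranges to named gene segments, ``subset_scheme`` maps each segment to
    one subset of the partitioning scheme, and ``subset_models`` gives
    each subset its substitution model tag ("GTR+G" or "GTR+I+G").
    """

    taxa: list[str]
    sites: np.ndarray                       # (n_taxa, n_sites) uint8
    segment_map: list[tuple[str, int, int]]  # (name, start, stop)
    subset_scheme: dict[str, int]
    subset_models: dict[int, str]

    def __post_init__(self):
        self.sites = np.asarray(self.sites, dtype=np.uint8)
        self.validate()

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.sites.shape[1] if self.sites.size else 0

    def validate(self) -> None:
        if self.sites.ndim != 2 or self.sites.shape[0] != len(self.taxa):
            raise CharacterDataError("sites array does not match taxa")
        covered = np.zeros(self.n_sites, dtype=int)
        for name, start, stop in self.segment_map:
            if not (0 <= start < stop <= self.n_sites):
                raise CharacterDataError(f"segment {name}: bad range")
            covered[start:stop] += 1
            if name not in self.subset_scheme:
                raise CharacterDataError(f"segment {name}: no subset assigned")
        if self.segment_map and not np.all(covered == 1):
            raise CharacterDataError("segments do not partition the alignment")
        used = set(self.subset_scheme.values())
        for sub in used:
            if sub not in self.subset_models:
                raise CharacterDataError(f"subset {sub}: no model assigned")

    @property
    def n_subsets(self) -> int:
        return len(set(self.subset_scheme.values()))

    def subset_sites(self, subset: int) -> np.ndarray:
        """Column indices belonging to one subset of the scheme."""
        cols = []
        for name, start, stop in self.segment_map:
            if self.subset_scheme[name] == subset:
                cols.append(np.arange(start, stop))
        return np.concatenate(cols) if cols else np.empty(0, dtype=int)

    def cell_count(self) -> int:
        return int((self.sites < 4).sum())


def encode_sequences(seqs: dict[str, str]):
    """Encode an {name: sequence} mapping to (taxa, uint8 array)."""
    taxa = list(seqs)
    n = len(next(iter(seqs.values()))) if seqs else 0
    arr = np.full((len(taxa), n), 4, dtype=np.uint8)
    for i, t in enumerate(taxa):
        s = seqs[t].upper()
        if len(s) != n:
            raise CharacterDataError(f"{t}: unaligned sequence length")
        for j, ch in enumerate(s):
            arr[i, j] = _NUC.get(ch, 4)
    return taxa, arr


def read_molecular_nexus(path, segment_map=None, subset_scheme=None,
                         subset_models=None) -> MolecularSupermatrix:
    """Read a DNA NEXUS alignment; partition scheme supplied as config."""
    try:
        dmat = dendropy.DnaCharacterMatrix.get(path=str(path), schema="nexus")
    except Exception as exc:
        raise CharacterDataError(f"NEXUS parse error in {path}: {exc}") from exc
    seqs = {normalize_name(t.label): str(dmat[t]) for t in dmat}
    taxa, arr = encode_sequences(seqs)
    n = arr.shape[1]
    if segment_map is None:
        segment_map = [("all", 0, n)]
    if subset_scheme is None:
        subset_scheme = {name: 0 for name, _, _ in segment_map}
    if subset_models is None:
        subset_models = {s: "GTR+G" for s in set(subset_scheme.values())}
    sm = MolecularSupermatrix(taxa, arr, segment_map, subset_scheme,
                              subset_models)
    logger.info("read %s: %d taxa x %d sites, %d segments, %d subsets",
                path, sm.n_taxa, sm.n_sites, len(segment_map), sm.n_subsets)
    return sm


def read_taxon_metadata(path) -> list[TaxonRecord]:
    """Read taxon metadata CSV/TSV: name, extant, min_Ma, max_Ma[, area]."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"name", "extant", "min_Ma", "max_Ma"}
    if not required.issubset(df.columns):
        raise CharacterDataError(
            f"metadata needs columns {sorted(required)}, got "
            f"{list(df.columns)}")
    records = []
    for _, row in df.iterrows():
        area = row.get("area")
        if isinstance(area, float) and np.isnan(area):
            area = None
        records.append(TaxonRecord(
            name=normalize_name(str(row["name"])),
            extant=bool(row["extant"]),
            age_window=(float(row["min_Ma"]), float(row["max_Ma"])),
            area=area))
    logger.info("read %s: %d taxon records", path, len(records))
    return records


def write_taxon_metadata(records, path) -> None:
    df = pd.DataFrame([
        {"name": r.name, "extant": r.extant, "min_Ma": r.age_window[0],
         "max_Ma": r.age_window[1], "area": r.area}
        for r in records])
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Combined dataset


@dataclass
class CombinedDataset:
    """Concatenated morphology + molecules + metadata + hard constraints.

    ``constraints`` is a list of ``(label, frozenset_of_taxa)`` clades
    enforced as monophyletic during inference (the study used primate
    monophyly and a scandentian outgroup).
    """

    morph: MorphMatrix | None
    mol: MolecularSupermatrix | None
    taxa: list[TaxonRecord]
    constraints: list[tuple[str, frozenset]] = field(default_factory=list)

    def __post_init__(self):
        names = {t.name for t in self.taxa}
        for src in (self.morph, self.mol):
            if src is not None and not set(src.taxa).issubset(names):
                missing = set(src.taxa) - names
                raise CharacterDataError(
                    f"taxa without metadata: {sorted(missing)[:5]}")
        if not any(t.extant for t in self.taxa):
            raise CharacterDataError("need at least one extant taxon")
        for label, clade in self.constraints:
            if not set(clade).issubset(names):
                raise CharacterDataError(
                    f"constraint {label}: unknown taxa {set(clade) - names}")

    @property
    def taxon_names(self) -> list[str]:
        return [t.name for t in self.taxa]

    @property
    def n_partitions(self) -> int:
        n = 0
        if self.morph is not None and self.morph.n_chars:
            n += 1
        if self.mol is not None and self.mol.n_sites:
            n += self.mol.n_subsets
        return n

    def record(self, name: str) -> TaxonRecord:
        for t in self.taxa:
            if t.name == name:
                return t
        raise KeyError(name)


def concatenate(morph: MorphMatrix | None,
                mol: MolecularSupermatrix | None,
                taxa: list[TaxonRecord],
                constraints=()) -> CombinedDataset:
    """Combine the data sources onto one taxon namespace.

    Taxa present in only one source get all-missing rows in the other;
    the result carries one morphological partition plus one partition
    per molecular subset.
    """
    names = [t.name for t in taxa]
    name_set = set(names)
    morph_taxa = set(morph.taxa) if morph is not None else set()
    mol_taxa = set(mol.taxa) if mol is not None else set()
    if morph is not None and mol is not None and mol.n_sites:
        if not morph_taxa & mol_taxa:
            raise CharacterDataError(
                "zero taxa shared between the morphological and molecular "
                "matrices; resolve the namespaces first")

    out_morph = morph
    if morph is not None:
        rows = []
        by_name = dict(zip(morph.taxa, morph.cells))
        for n in names:
            rows.append(list(by_name.get(n, [MISSING] * morph.n_chars)))
        out_morph = MorphMatrix(
            taxa=list(names), cells=rows, n_states=morph.n_states.copy(),
            ordered=morph.ordered.copy(),
            recoded_flags=morph.recoded_flags.copy(),
            _recode_done=morph._recode_done.copy())

    out_mol = mol
    if mol is not None and mol.n_sites:
        arr = np.full((len(names), mol.n_sites), 4, dtype=np.uint8)
        by_name = {t: i for i, t in enumerate(mol.taxa)}
        for i, n in enumerate(names):
            if n in by_name:
                arr[i] = mol.sites[by_name[n]]
        out_mol = MolecularSupermatrix(
            list(names), arr, list(mol.segment_map), dict(mol.subset_scheme),
            dict(mol.subset_models))

    ds = CombinedDataset(morph=out_morph, mol=out_mol, taxa=list(taxa),
                         constraints=list(constraints))
    logger.info("combined dataset: %d taxa, %d partitions",
                len(names), ds.n_partitions)
    return ds


def extant_sampling_fraction(n_sampled_extant: int,
                             clade_richness) -> float:
    """Proportion of living diversity sampled: n / sum(richness).

    This is the fixed extant sampling probability rho of the
    fossilized-birth-death prior.
    """
    total = int(np.sum(np.asarray(list(clade_richness), dtype=int)))
    if n_sampled_extant <= 0 or total <= 0:
        raise CharacterDataError("counts must be positive")
    frac = n_sampled_extant / total
    if frac > 1:
        raise CharacterDataError(
            f"sampled extant taxa ({n_sampled_extant}) exceed total "
            f"richness ({total})")
    return frac
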