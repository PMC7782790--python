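"""Segregant-group calling on single-cell pedigrees.

A budding-yeast mother cell is dissected at every division: daughter ``Dn``
is moved away, then ``Dn``'s first and second daughters (``GDn.1``,
``GDn.2``) and ``GDn.1``'s first daughter (``GGDn.1``) are isolated, so each
maternal division ``n`` is represented by a four-colony *sublineage*.
Replication errors made during division ``n`` are single-strand mismatches
for one cell cycle and become double-stranded mutations at the next
division, landing in one of four segregant groups with characteristic
presence/absence patterns across the colonies:

* ``Da(n)`` -- retained by the daughter: present in ``Dn`` and ``GDn.2``.
* ``Db(n)`` -- passed to the first granddaughter: in ``GDn.1``, ``GGDn.1``.
* ``Ma(n)`` -- passed to the mother's next daughter: in every colony of
  sublineage ``n+1``.
* ``Mb(n)`` -- retained by the mother: in every colony of every sublineage
  ``>= n+2``.

``Da+Db`` (= ``Dm``) and ``Ma+Mb`` (= ``Mm``) are the mismatches segregated
to daughter and mother; their sum is the division's full error count.
Requiring each mutation in at least two colonies removes sequencing-error
singletons.  Deviations from the patterns reveal colonies placed at the
wrong pedigree position ("assignment errors"), and the per-chromosome
all-or-none split of each pair of segregant groups exposes the mitotic
segregation of whole mutation-bearing chromatids.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import intervals as ivl
from .genome import ChromosomeSet

__all__ = [
    "POSITIONS", "Role", "ColonyRecord", "LineageTable", "SegregantCounts",
    "SegregationTally", "AssignmentErrorFlag",
    "shared_callable_genome", "filter_to_shared", "assign_segregant_groups",
    "full_error_count", "mismatch_counts", "detect_assignment_errors",
    "classify_segregation", "tally_segregation", "call_lineage",
]

POSITIONS = ("D", "GD1", "GD2", "GGD")

Variant = tuple[str, int, str, str]  # chrom, 0-based pos, ref, alt


@dataclass(frozen=True)
class Role:
    """Pedigree role of a colony: maternal division index and position."""
    division: int
    position: str

    def __post_init__(self):
        if self.division < 1:
            raise ValueError("division index must be >= 1")
        if self.position not in POSITIONS:
            raise ValueError(f"position must be one of {POSITIONS}")


@dataclass
class ColonyRecord:
    colony_id: str
    role: Role
    variants: set[Variant]
    callable: ivl.IntervalMap

    def __post_init__(self):
        self.callable = ivl.normalize_map(self.callable)


class LineageTable:
    """Ordered pedigree of four-colony sublineages plus a karyotype.

    Sublineages are numbered consecutively from 1; a sublineage can be
    marked censored (e.g. after an assignment error is flagged), which
    removes its colonies from pattern evaluation.
    """

    def __init__(self, records: list[ColonyRecord], chromset: ChromosomeSet,
                 censored=()):
        self.chromset = chromset
        self._by_division: dict[int, dict[str, ColonyRecord]] = {}
        for rec in records:
            sub = self._by_division.setdefault(rec.role.division, {})
            if rec.role.position in sub:
                raise ValueError(
                    f"duplicate colony for division {rec.role.division} "
                    f"position {rec.role.position}"
                )
            sub[rec.role.position] = rec
        divisions = sorted(self._by_division)
        if divisions != list(range(1, len(divisions) + 1)):
            raise ValueError("sublineages must be numbered 1..N consecutively")
        for n, sub in self._by_division.items():
            missing = set(POSITIONS) - sub.keys()
            if missing:
                raise ValueError(f"sublineage {n} missing positions {missing}")
        self.censored: set[int] = set(censored)
        for chrom, pos, *_ in self.iter_variants():
            if chrom not in chromset.names:
                raise ValueError(f"variant on unknown chromosome {chrom!r}")
            if not 0 <= pos < chromset.length_of(chrom):
                raise ValueError(f"variant position {pos} outside {chrom}")

    # -- structure ----------------------------------------------------------
    @property
    def n_divisions(self) -> int:
        return len(self._by_division)

    def divisions(self) -> list[int]:
        return sorted(self._by_division)

    def sublineage(self, n: int) -> dict[str, ColonyRecord]:
        return self._by_division[n]

    def colony(self, n: int, position: str) -> ColonyRecord:
        return self._by_division[n][position]

    def colonies(self) -> list[ColonyRecord]:
        return [self._by_division[n][p] for n in self.divisions()
                for p in POSITIONS]

    def active_colonies(self) -> list[ColonyRecord]:
        """Colonies of uncensored sublineages only."""
        return [self._by_division[n][p] for n in self.divisions()
                if n not in self.censored for p in POSITIONS]

    def iter_variants(self):
        seen: set[Variant] = set()
        for rec in self.colonies():
            for v in rec.variants:
                if v not in seen:
                    seen.add(v)
                    yield v

    def is_scorable(self, n: int) -> bool:
        """Division ``n`` needs sublineages ``n..n+3`` present, uncensored."""
        need = range(n, n + 4)
        return all(m in self._by_division and m not in self.censored
                   for m in need)

    def replace(self, records=None, censored=None) -> "LineageTable":
        recs = records if records is not None else self.colonies()
        cens = censored if censored is not None else self.censored
        new = LineageTable(recs, self.chromset, cens)
        return new


# ---------------------------------------------------------------------------
# shared genome and filtering

def shared_callable_genome(lineage: LineageTable, members=None):
    """Intersect the callable intervals of a set of colonies.

    Returns ``(interval_map, per_chromosome_lengths)``.  ``members`` is an
    iterable of colony ids (default: every colony in the lineage).
    """
    colonies = lineage.colonies()
    if members is not None:
        members = set(members)
        if not members:
            raise ValueError("empty member list")
        by_id = {c.colony_id: c for c in colonies}
        unknown = members - by_id.keys()
        if unknown:
            raise ValueError(f"unknown colony ids: {sorted(unknown)}")
        colonies = [by_id[m] for m in members]
    shared = ivl.intersect_maps([c.callable for c in colonies])
    lengths = {chrom: ivl.total_length(ivs) for chrom, ivs in shared.items()}
    return shared, lengths


def filter_to_shared(lineage: LineageTable) -> LineageTable:
    """Restrict every colony to the shared callable genome and drop
    singletons (variants observed in only one colony of the lineage)."""
    shared, _ = shared_callable_genome(lineage)
    counts: dict[Variant, int] = {}
    for rec in lineage.colonies():
        for v in rec.variants:
            if v[0] in shared and ivl.contains(shared[v[0]], v[1]):
                counts[v] = counts.get(v, 0) + 1
    keep = {v for v, c in counts.items() if c >= 2}
    records = [
        ColonyRecord(rec.colony_id, rec.role, rec.variants & keep,
                     {c: list(iv) for c, iv in shared.items()})
        for rec in lineage.colonies()
    ]
    return LineageTable(records, lineage.chromset, lineage.censored)


# ---------------------------------------------------------------------------
# segregant-group assignment

GROUPS = ("Da", "Db", "Ma", "Mb")


@dataclass
class SegregantCounts:
    """Per-division segregant-group tallies.

    ``per_chromosome`` holds the four counts per chromosome (rows in
    karyotype order); the scalar counts are its column sums.  ``unassigned``
    collects variants whose earliest-presence pattern implicates this
    division but that match no group's pattern (never silently dropped).
    """
    division: int
    scorable: bool
    da: int = 0
    db: int = 0
    ma: int = 0
    mb: int = 0
    per_chromosome: pd.DataFrame | None = None
    unassigned: set = field(default_factory=set)
    assignments: dict = field(default_factory=dict)  # variant -> group

    @property
    def dm(self) -> int:
        return self.da + self.db

    @property
    def mm(self) -> int:
        return self.ma + self.mb

    @property
    def full(self) -> int:
        return self.da + self.db + self.ma + self.mb


def full_error_count(sc: SegregantCounts) -> int:
    """Full replication error count of the division: Da+Db+Ma+Mb."""
    return sc.full


def mismatch_counts(sc: SegregantCounts):
    """Mismatches segregated to daughter and mother: (Dm, Mm)."""
    return sc.dm, sc.mm


def _presence_patterns(lineage: LineageTable):
    """Group variants by their exact colony-presence pattern (active
    colonies only).  Returns dict[frozenset[colony_id], set[Variant]]."""
    pres: dict[Variant, set[str]] = {}
    for rec in lineage.active_colonies():
        for v in rec.variants:
            pres.setdefault(v, set()).add(rec.colony_id)
    patterns: dict[frozenset, set[Variant]] = {}
    for v, cols in pres.items():
        patterns.setdefault(frozenset(cols), set()).add(v)
    return patterns


def _ids(lineage: LineageTable, n: int) -> dict[str, str]:
    return {p: lineage.colony(n, p).colony_id for p in POSITIONS}


def _group_pattern(lineage: LineageTable, n: int, group: str) -> frozenset:
    """Expected exact presence pattern of a group of division ``n``."""
    if group == "Da":
        ids = _ids(lineage, n)
        return frozenset((ids["D"], ids["GD2"]))
    if group == "Db":
        ids = _ids(lineage, n)
        return frozenset((ids["GD1"], ids["GGD"]))
    if group == "Ma":
        return frozenset(_ids(lineage, n + 1).values())
    if group == "Mb":
        later = [m for m in lineage.divisions()
                 if m >= n + 2 and m not in lineage.censored]
        return frozenset(cid for m in later
                         for cid in _ids(lineage, m).values())
    raise ValueError(group)


def _implicated_division(lineage: LineageTable, pattern: frozenset) -> int | None:
    """Earliest-presence heuristic mapping a pattern to the division whose
    groups it could have come from (used to attribute unassigned residue)."""
    division_of = {lineage.colony(n, p).colony_id: n
                   for n in lineage.divisions() if n not in lineage.censored
                   for p in POSITIONS}
    subs = sorted({division_of[cid] for cid in pattern if cid in division_of})
    if not subs:
        return None
    first = subs[0]
    if len(subs) == 1:
        ids = set(_ids(lineage, first).values())
        if pattern == frozenset(ids):
            return first - 1  # Ma-like: spans one full sublineage
        return first         # Da/Db-like: within one sublineage
    return first - 2          # Mb-like: spans several, first appears at n+2


def assign_segregant_groups(lineage: LineageTable, n: int,
                            _patterns=None, _implicated=None) -> SegregantCounts:
    """Classify division ``n``'s mutations into Da/Db/Ma/Mb by their exact
    presence pattern across the (filtered) lineage.

    The division is scorable only when sublineages ``n..n+3`` are present
    and uncensored; otherwise a non-scorable record is returned (counts are
    censored, not zero).  Variants implicating the division but matching no
    pattern land in ``unassigned``.
    """
    if not lineage.is_scorable(n):
        return SegregantCounts(division=n, scorable=False)
    patterns = _patterns if _patterns is not None else _presence_patterns(lineage)
    chroms = list(lineage.chromset.names)
    per_chrom = {g: Counter() for g in GROUPS}
    assignments: dict[Variant, str] = {}
    counts = {}
    for group in GROUPS:
        expect = _group_pattern(lineage, n, group)
        matched = patterns.get(expect, set())
        counts[group] = len(matched)
        for v in matched:
            assignments[v] = group
            per_chrom[group][v[0]] += 1
    table = pd.DataFrame(
        {g: [per_chrom[g].get(c, 0) for c in chroms] for g in GROUPS},
        index=chroms,
    )
    if _implicated is None:
        _implicated = {p: _implicated_division(lineage, p) for p in patterns}
    unassigned = set()
    for pattern, variants in patterns.items():
        if _implicated.get(pattern) == n:
            unmatched = {v for v in variants if v not in assignments}
            unassigned |= unmatched
    return SegregantCounts(
        division=n, scorable=True,
        da=counts["Da"], db=counts["Db"], ma=counts["Ma"], mb=counts["Mb"],
        per_chromosome=table, unassigned=unassigned, assignments=assignments,
    )


# ---------------------------------------------------------------------------
# assignment-error detection

@dataclass(frozen=True)
class AssignmentErrorFlag:
    division: int
    signature: str  # "ma_zero_recurring_db" | "mb_zero" | "da_matches_ma"
    detail: str
    suggested_censor: tuple[int, ...]


def _colony_variant_index(lineage: LineageTable):
    pres: dict[Variant, set[str]] = {}
    for rec in lineage.active_colonies():
        for v in rec.variants:
            pres.setdefault(v, set()).add(rec.colony_id)
    return pres


def detect_assignment_errors(lineage: LineageTable,
                             recurrence_threshold: float = 0.25,
                             min_support: int = 3) -> list[AssignmentErrorFlag]:
    """Scan a filtered lineage for the documented mis-dissection signatures.

    * ``ma_zero_recurring_db`` -- a mother's daughter was moved in place of a
      granddaughter: the sublineage's Ma group is empty while more than
      ``recurrence_threshold`` of its putative Db variants recur in later
      sublineages (a true swap sends ~50% downstream; stray noise ~0%).
    * ``mb_zero`` -- a sublineage whose members all descend from one daughter
      shows an empty Mb group despite a mutation load that makes an empty
      group implausible.
    * ``da_matches_ma`` -- the two granddaughters were swapped: the strict Da
      and Db groups empty out and the daughter-retained mutations surface
      with a presence pattern confined to the D and GD1 colonies.

    Returns one flag per (division, signature); clean lineages return [].
    """
    flt = filter_to_shared(lineage)
    patterns = _presence_patterns(flt)
    pres = _colony_variant_index(flt)
    divisions = [n for n in flt.divisions() if n not in flt.censored]
    n_max = max(divisions, default=0)
    # guard for the weak-evidence signatures: lineage-wide mutation load
    mean_load = (len(pres) / max(len(divisions), 1)) if pres else 0.0
    flags: list[AssignmentErrorFlag] = []

    def censor_range(lo: int, hi: int) -> tuple[int, ...]:
        return tuple(m for m in range(lo, hi + 1) if m in divisions)

    for s in divisions:
        ids = _ids(flt, s)
        sub_ids = set(ids.values())
        later_cols = {cid for m in divisions if m > s
                      for cid in _ids(flt, m).values()}
        earlier_cols = {cid for m in divisions if m < s
                        for cid in _ids(flt, m).values()}

        # signature (a): Ma group observed in sublineage s is empty while
        # putative Db variants of s recur downstream
        if s >= 2 and s < n_max:
            ma_observed = len(patterns.get(frozenset(sub_ids), set()))
            putative_db = {
                v for v, cols in pres.items()
                if ids["GD1"] in cols and ids["GGD"] in cols
                and ids["D"] not in cols and ids["GD2"] not in cols
                and not (cols & earlier_cols)
            }
            if ma_observed == 0 and len(putative_db) >= min_support:
                recur = {v for v in putative_db if pres[v] & later_cols}
                frac = len(recur) / len(putative_db)
                if frac > recurrence_threshold:
                    flags.append(AssignmentErrorFlag(
                        division=s, signature="ma_zero_recurring_db",
                        detail=(f"Ma group of sublineage {s} is empty and "
                                f"{frac:.0%} of putative Db variants recur "
                                "in later sublineages"),
                        suggested_censor=censor_range(s - 3, s + 1),
                    ))

        # signature (b): Mb group first appearing in sublineage s is empty
        if 3 <= s < n_max and mean_load >= 10:
            mb_pattern = _group_pattern(flt, s - 2, "Mb")
            if len(patterns.get(mb_pattern, set())) == 0:
                flags.append(AssignmentErrorFlag(
                    division=s, signature="mb_zero",
                    detail=(f"no mutations shared by all sublineages >= {s}: "
                            "its members may all descend from one daughter"),
                    suggested_censor=censor_range(s - 3, s),
                ))

        # signature (c): granddaughter swap.  The strict Da group empties
        # while the variants at the Da branch point (shared by D and GD2,
        # first appearing in this sublineage) are all present in the whole
        # sublineage, i.e. they follow the Ma pattern of division s-1.
        da = len(patterns.get(_group_pattern(flt, s, "Da"), set()))
        putative_da = {
            v for v, cols in pres.items()
            if ids["D"] in cols and ids["GD2"] in cols
            and not (cols & earlier_cols) and not (cols & later_cols)
        }
        if da == 0 and len(putative_da) >= min_support:
            ma_like = {v for v in putative_da if pres[v] == sub_ids}
            frac = len(ma_like) / len(putative_da)
            if frac > 0.9:
                flags.append(AssignmentErrorFlag(
                    division=s, signature="da_matches_ma",
                    detail=(f"division {s}: Da group empty and {frac:.0%} of "
                            "the variants at the Da branch point follow the "
                            f"Ma pattern of division {s - 1} (granddaughter "
                            "swap)"),
                    suggested_censor=censor_range(s - 3, s),
                ))
    return flags


# ---------------------------------------------------------------------------
# per-chromosome segregation classes

@dataclass
class SegregationTally:
    """Counts of per-chromosome-per-division segregation classes.

    ``all``: the first group of the pair holds 100% of the chromosome's
    mutations; ``none``: 0%; ``partial``: any strictly intermediate
    fraction.  Chromosomes with zero mutations in the pair are excluded.
    """
    none: int = 0
    partial: int = 0
    all: int = 0
    fractions: list[float] = field(default_factory=list)

    def __add__(self, other: "SegregationTally") -> "SegregationTally":
        return SegregationTally(self.none + other.none,
                                self.partial + other.partial,
                                self.all + other.all,
                                self.fractions + other.fractions)

    @property
    def total(self) -> int:
        return self.none + self.partial + self.all

    def as_array(self) -> np.ndarray:
        return np.array([self.none, self.partial, self.all])


_PAIRS = {"Da/Db": ("Da", "Db"), "Ma/Mb": ("Ma", "Mb")}


def classify_segregation(sc: SegregantCounts, pair: str = "Da/Db") -> SegregationTally:
    """Per-chromosome all/partial/none inheritance classes for one division.

    For each chromosome with at least one mutation in the pair, the fraction
    observed in the first group is computed; 1 -> "all", 0 -> "none",
    otherwise "partial".  Under independent all-or-none segregation of two
    homologous copies the classes follow the Mendelian 1:2:1 ratio.
    """
    if pair not in _PAIRS:
        raise ValueError(f"pair must be one of {sorted(_PAIRS)}")
    if sc.per_chromosome is None:
        raise ValueError("division is not scorable: no per-chromosome counts")
    a, b = _PAIRS[pair]
    tally = SegregationTally()
    for _, row in sc.per_chromosome.iterrows():
        total = row[a] + row[b]
        if total == 0:
            continue
        frac = row[a] / total
        tally.fractions.append(float(frac))
        if frac == 1.0:
            tally.all += 1
        elif frac == 0.0:
            tally.none += 1
        else:
            tally.partial += 1
    return tally


def tally_segregation(counts: list[SegregantCounts], pair: str = "Da/Db") -> SegregationTally:
    """Accumulate segregation classes across divisions."""
    out = SegregationTally()
    for sc in counts:
        if sc.scorable:
            out = out + classify_segregation(sc, pair)
    return out


# ---------------------------------------------------------------------------
# driver

def call_lineage(lineage: LineageTable, detect_errors: bool = True):
    """Filter, censor flagged sublineages, and score every division.

    Returns ``(counts, flags)`` where ``counts`` is a list of
    :class:`SegregantCounts` for divisions ``1..N-3`` (non-scorable
    divisions included with ``scorable=False``) computed on the filtered,
    censored lineage.
    """
    flags = detect_assignment_errors(lineage) if detect_errors else []
    censored = set(lineage.censored)
    for flag in flags:
        censored.update(flag.suggested_censor)
        censored.add(flag.division)
    flt = filter_to_shared(lineage.replace(censored=censored))
    patterns = _presence_patterns(flt)
    implicated = {p: _implicated_division(flt, p) for p in patterns}
    counts = [assign_segregant_groups(flt, n, _patterns=patterns,
                                      _implicated=implicated)
              for n in range(1, max(flt.n_divisions - 2, 1))]
    return counts, flags
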