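"""Forward simulation of single-cell mutator pedigrees with known truth.

The generator runs the same mechanism the lineage caller is built to read
out.  Every cell division ``d`` (of any cell in the pedigree):

1. draws a genome-wide per-side rate ``lambda_d ~ Gamma(shape=theta,
   mean=mu)`` -- the division-variant volatility model;
2. lays down Poisson mismatches independently on the mother-retained and the
   daughter-bound nascent genome, per chromosome copy at rate
   ``lambda_d * f_c / ploidy`` (``f_c`` the chromosome's genome fraction);
3. at the cell's *next* division, each chromosome copy's batch of pending
   mismatches becomes double-stranded mutations on one of the two new
   duplexes, which segregates all-or-none by a Bernoulli(1/2) draw to the
   new daughter or is retained -- fixing the Da/Db (daughter side) or Ma/Mb
   (mother side) identity of every maternal-division mutation;
4. double-stranded mutations are inherited by all later offspring.

A colony's variant list is the set of double-stranded mutations carried by
its founder cell when it is finally left to grow (later mutations are
sub-clonal and, like sequencing errors, are modelled by the colony-private
singleton noise channel).  Mismatches never resolved before the pedigree
ends are dropped.

Because descendants of each daughter are also simulated, the documented
dissection mix-ups can be replayed exactly: ``inject_assignment_error``
rebuilds the emitted colonies from the same simulated ground truth with the
mis-dissected cells in the wrong pedigree slots.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import ChromosomeSet, builtin_karyotype
from .lineage import ColonyRecord, LineageTable, Role

__all__ = ["GroundTruth", "generate_lineage", "inject_assignment_error",
           "generate_count_sample", "ERROR_TYPES"]

ERROR_TYPES = ("Dn1_for_GDn1", "GDn1_GDn2_swap", "GGDn1_GGDn2_swap")

_REF = "C"
_ALTS = ("A", "G", "T")


@dataclass
class GroundTruth:
    """Complete record of one simulated pedigree.

    ``events`` lists every double-stranded mutation ever fixed in the
    pedigree (maternal-division events carry a Da/Db/Ma/Mb label and the
    division they arose in; events from descendant divisions are unlabeled
    and reach at most one emitted colony).  ``snapshots`` maps
    ``(cell, k)`` to the set of event ids double-stranded in that cell after
    its k-th division, which is what a colony founded at that point
    propagates clonally.
    """
    chromset: ChromosomeSet
    n_divisions: int
    mu: float
    theta: float
    ploidy: int
    noise_rate: float
    masking_fraction: float
    seed: int | None
    lambdas: np.ndarray  # per maternal division, per-side rate
    events: list  # id -> (chrom, pos, ref, alt)
    labels: list  # id -> "Da"/"Db"/"Ma"/"Mb"/None
    event_division: list  # id -> maternal division, or 0 for descendants
    snapshots: dict  # (cell_name, k) -> frozenset of event ids
    occupied: dict  # chrom index -> set of positions in use

    def variant_truth(self) -> dict:
        """Map variant tuple -> (group label, division) for labeled events."""
        return {
            self.events[i]: (self.labels[i], self.event_division[i])
            for i in range(len(self.events))
            if self.labels[i] is not None
        }

    def expected_counts(self, n: int) -> dict[str, int]:
        """Truth tallies of the four segregant groups for division ``n``."""
        out = {"Da": 0, "Db": 0, "Ma": 0, "Mb": 0}
        for lbl, d in zip(self.labels, self.event_division):
            if d == n and lbl is not None:
                out[lbl] += 1
        return out

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            {"chrom": ev[0], "pos": ev[1] + 1, "ref": ev[2], "alt": ev[3],
             "division": d, "group": lbl}
            for ev, lbl, d in zip(self.events, self.labels, self.event_division)
            if lbl is not None
        ]
        return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                           "division", "group"])


class _Cell:
    __slots__ = ("name", "ds", "pending", "n_divs")

    def __init__(self, name: str, ds: set[int]):
        self.name = name
        self.ds = ds
        # pending mismatch batches: list of (label_spec, {copy: [event ids]})
        # label_spec = (retained_label, passed_label, division) or None
        self.pending: list[tuple] = []
        self.n_divs = 0


class _Simulation:
    def __init__(self, chromset, mu, theta, ploidy, rng):
        self.chromset = chromset
        self.ploidy = ploidy
        self.mu = mu
        self.theta = theta
        self.rng = rng
        self.copy_rates = np.repeat(chromset.fractions_array(), ploidy) / ploidy
        self.lengths = np.asarray(chromset.lengths_bp)
        self.events: list = []
        self.labels: list = []
        self.event_division: list = []
        self.occupied: dict[int, set[int]] = {
            i: set() for i in range(chromset.n_chromosomes)
        }
        self.snapshots: dict = {}
        self.cells: dict[str, _Cell] = {"M": _Cell("M", set())}

    def draw_lambda(self) -> float:
        return float(self.rng.gamma(self.theta, self.mu / self.theta))

    def _alloc_positions(self, chrom_i: int, k: int) -> list[int]:
        occ = self.occupied[chrom_i]
        length = int(self.lengths[chrom_i])
        out: list[int] = []
        while len(out) < k:
            for p in self.rng.integers(0, length, size=k - len(out)):
                p = int(p)
                if p not in occ:  # positions unique within a lineage
                    occ.add(p)
                    out.append(p)
        return out

    def _new_batch(self, lam: float) -> dict[int, list[int]]:
        counts = self.rng.poisson(lam * self.copy_rates)
        batch: dict[int, list[int]] = {}
        names = self.chromset.names
        for copy_i in np.nonzero(counts)[0]:
            k = int(counts[copy_i])
            chrom_i = int(copy_i) // self.ploidy
            positions = self._alloc_positions(chrom_i, k)
            alts = self.rng.integers(0, 3, size=k)
            ids = []
            for pos, a in zip(positions, alts):
                ids.append(len(self.events))
                self.events.append((names[chrom_i], pos, _REF, _ALTS[a]))
                self.labels.append(None)
                self.event_division.append(0)
            batch[int(copy_i)] = ids
        return batch

    def divide(self, parent_name: str, daughter_name: str,
               lam: float, maternal_division: int | None = None) -> None:
        """One division: resolve pending mismatches, create new ones."""
        parent = self.cells[parent_name]
        daughter = _Cell(daughter_name, set(parent.ds))
        # pending mismatches become double-stranded mutations; per chromosome
        # copy the mutation-bearing duplex segregates all-or-none
        for label_spec, batch in parent.pending:
            for ids in batch.values():
                passed = bool(self.rng.integers(0, 2))
                target = daughter.ds if passed else parent.ds
                target.update(ids)
                if label_spec is not None:
                    retained_lbl, passed_lbl, division = label_spec
                    lbl = passed_lbl if passed else retained_lbl
                    for i in ids:
                        self.labels[i] = lbl
                        self.event_division[i] = division
        parent.pending = []
        # fresh mismatches on both nascent genomes
        if maternal_division is not None:
            mother_spec = ("Mb", "Ma", maternal_division)
            daughter_spec = ("Da", "Db", maternal_division)
        else:
            mother_spec = daughter_spec = None
        parent.pending.append((mother_spec, self._new_batch(lam)))
        daughter.pending.append((daughter_spec, self._new_batch(lam)))
        parent.n_divs += 1
        self.cells[daughter_name] = daughter
        if parent_name != "M":
            self.snapshots[(parent_name, parent.n_divs)] = frozenset(parent.ds)
        self.snapshots[(daughter_name, 0)] = frozenset(daughter.ds)


def _cell_key(seed, cell: str, k: int, salt: int):
    """Stable per-colony RNG so clean and corrupted emissions of the same
    physical cell share noise and callable masks."""
    base = 0 if seed is None else int(seed) % (2**31 - 1)
    return np.random.default_rng(
        [base, zlib.crc32(cell.encode()) % (2**31 - 1), k, salt]
    )


def _colony_callable(chromset, masking_fraction, seed, cell, k):
    if masking_fraction <= 0:
        return {name: [(0, length)]
                for name, length in zip(chromset.names, chromset.lengths_bp)}
    rng = _cell_key(seed, cell, k, 1)
    out = {}
    for name, length in zip(chromset.names, chromset.lengths_bp):
        w = int(masking_fraction * length)
        start = int(rng.integers(0, length - w)) if w > 0 else 0
        out[name] = [(0, start), (start + w, length)]
    return out


def _colony_noise(truth_occupied, chromset, noise_rate, seed, cell, k):
    """Colony-private singleton variants (sequencing errors, sub-clonal
    mutations); positions avoid true-event sites."""
    if noise_rate <= 0:
        return set()
    rng = _cell_key(seed, cell, k, 2)
    n = int(rng.poisson(noise_rate))
    fracs = chromset.fractions_array()
    out = set()
    for _ in range(n):
        chrom_i = int(rng.choice(chromset.n_chromosomes, p=fracs))
        length = chromset.lengths_bp[chrom_i]
        pos = int(rng.integers(0, length))
        while pos in truth_occupied[chrom_i]:
            pos = int(rng.integers(0, length))
        alt = _ALTS[int(rng.integers(0, 3))]
        out.add((chromset.names[chrom_i], pos, _REF, alt))
    return out


# slot layout: position -> (cell name, snapshot index) for sublineage n
def _clean_slots(n: int) -> dict[str, tuple[str, int]]:
    return {
        "D": (f"D{n}", 2),
        "GD1": (f"GD{n}.1", 1),
        "GD2": (f"GD{n}.2", 0),
        "GGD": (f"GGD{n}.1", 0),
    }


def _slot_id(n: int, position: str) -> str:
    return {"D": f"D{n}", "GD1": f"GD{n}.1",
            "GD2": f"GD{n}.2", "GGD": f"GGD{n}.1"}[position]


def _emit(truth: GroundTruth, slot_map: dict[int, dict[str, tuple[str, int]]]
          ) -> LineageTable:
    masked = truth.masking_fraction > 0
    records = []
    for n, slots in slot_map.items():
        for position, (cell, k) in slots.items():
            ids = truth.snapshots[(cell, k)]
            callable_map = _colony_callable(
                truth.chromset, truth.masking_fraction, truth.seed, cell, k)
            variants = {truth.events[i] for i in ids}
            variants |= _colony_noise(truth.occupied, truth.chromset,
                                      truth.noise_rate, truth.seed, cell, k)
            if masked:
                variants = {v for v in variants if _in_map(callable_map, v)}
            records.append(ColonyRecord(
                colony_id=_slot_id(n, position),
                role=Role(division=n, position=position),
                variants=variants, callable=callable_map,
            ))
    table = LineageTable(records, truth.chromset)
    table._truth = truth
    return table


def _in_map(callable_map, variant) -> bool:
    from . import intervals as ivl
    ivs = callable_map.get(variant[0])
    return ivs is not None and ivl.contains(ivs, variant[1])


def generate_lineage(n_divisions: int, mu: float = 138.0, theta: float = 60.42,
                     chromset: ChromosomeSet | None = None, ploidy: int = 2,
                     noise_rate: float = 0.0, masking_fraction: float = 0.0,
                     seed=None) -> tuple[LineageTable, GroundTruth]:
    """Simulate a pedigree of ``n_divisions`` maternal divisions.

    ``mu`` is the expected mismatch count per *segregant side* (the mean of
    the Dm/Mm marginal, the quantity the per-side negative-binomial fit
    estimates); the per-side rate ``lambda_n ~ Gamma(shape=theta, mean=mu)``
    is shared by the mother-retained and daughter-bound genomes of the
    division, so full error counts are negative-binomial with mean ``2*mu``
    and shape ``theta``.  Divisions
    ``n_divisions-2 .. n_divisions`` are unscorable by construction (their
    Ma/Mb groups need sublineages that were never isolated).

    Returns the emitted :class:`LineageTable` (colony variant lists plus
    callable intervals) and the :class:`GroundTruth`.
    """
    if n_divisions < 4:
        raise ValueError("need at least 4 divisions to score division 1")
    if mu <= 0 or theta <= 0:
        raise ValueError("mu and theta must be positive")
    if chromset is None:
        chromset = builtin_karyotype("yeast_s288c", ploidy=ploidy)
    elif chromset.ploidy != ploidy:
        chromset = chromset.with_ploidy(ploidy)
    rng = np.random.default_rng(seed)
    sim = _Simulation(chromset, mu, theta, ploidy, rng)

    lambdas = np.empty(n_divisions)
    for n in range(1, n_divisions + 1):
        lam = sim.draw_lambda()
        lambdas[n - 1] = lam
        sim.divide("M", f"D{n}", lam, maternal_division=n)
    # descendant divisions: same volatility model, unlabeled events; these
    # supply the material for replaying dissection mix-ups
    for n in range(1, n_divisions + 1):
        sim.divide(f"D{n}", f"GD{n}.1", sim.draw_lambda())
        sim.divide(f"D{n}", f"GD{n}.2", sim.draw_lambda())
        sim.divide(f"GD{n}.1", f"GGD{n}.1", sim.draw_lambda())
        sim.divide(f"GD{n}.1", f"GGD{n}.2", sim.draw_lambda())
        sim.divide(f"GD{n}.2", f"GGD{n}.2b", sim.draw_lambda())
        sim.divide(f"GGD{n}.1", f"GGGD{n}.1", sim.draw_lambda())

    truth = GroundTruth(
        chromset=chromset, n_divisions=n_divisions, mu=mu, theta=theta,
        ploidy=ploidy, noise_rate=noise_rate,
        masking_fraction=masking_fraction,
        seed=None if seed is None else int(seed),
        lambdas=lambdas, events=sim.events, labels=sim.labels,
        event_division=sim.event_division, snapshots=sim.snapshots,
        occupied=sim.occupied,
    )
    slot_map = {n: _clean_slots(n) for n in range(1, n_divisions + 1)}
    return _emit(truth, slot_map), truth


def inject_assignment_error(lineage: LineageTable, division: int,
                            error_type: str, truth: GroundTruth | None = None,
                            seed=None) -> LineageTable:
    """Rebuild the emitted lineage with a documented dissection mix-up.

    * ``Dn1_for_GDn1``: the mother's next daughter ``Dn+1`` is moved in
      place of ``GDn.1``; the displaced cells cascade into sublineage
      ``n+1`` (which then consists of ``GDn.1`` and its offspring).
    * ``GDn1_GDn2_swap``: the first and second granddaughters are reversed,
      so the great-granddaughter is taken from ``GDn.2``.
    * ``GGDn1_GGDn2_swap``: the second great-granddaughter is taken instead
      of the first -- the documented blind spot: no inheritance-pattern
      distortion, only a Db count drawn from two of ``GDn.1``'s divisions.
    """
    if error_type not in ERROR_TYPES:
        raise ValueError(f"unknown error_type {error_type!r}; "
                         f"choose from {ERROR_TYPES}")
    if truth is None:
        truth = getattr(lineage, "_truth", None)
    if truth is None:
        raise ValueError("ground truth required to replay a dissection error")
    n = division
    if not lineage.is_scorable(n):
        raise ValueError(f"division {n} is not scorable in the clean lineage")
    n_total = truth.n_divisions
    slot_map = {m: _clean_slots(m) for m in range(1, n_total + 1)}
    if error_type == "Dn1_for_GDn1":
        if n + 1 > n_total:
            raise ValueError("Dn1_for_GDn1 needs sublineage n+1")
        slot_map[n] = {
            "D": (f"D{n}", 2),
            "GD1": (f"D{n+1}", 1),        # Dn+1 mistaken for GDn.1
            "GD2": (f"GD{n}.2", 0),
            "GGD": (f"GD{n+1}.1", 0),     # its daughter taken as GGDn.1
        }
        slot_map[n + 1] = {
            "D": (f"GD{n}.1", 2),         # GDn.1 left in the Dn+1 spot
            "GD1": (f"GGD{n}.1", 1),
            "GD2": (f"GGD{n}.2", 0),
            "GGD": (f"GGGD{n}.1", 0),
        }
    elif error_type == "GDn1_GDn2_swap":
        slot_map[n] = {
            "D": (f"D{n}", 2),
            "GD1": (f"GD{n}.2", 1),       # second granddaughter first
            "GD2": (f"GD{n}.1", 0),
            "GGD": (f"GGD{n}.2b", 0),     # great-granddaughter from GDn.2
        }
    else:  # GGDn1_GGDn2_swap
        slot_map[n] = {
            "D": (f"D{n}", 2),
            "GD1": (f"GD{n}.1", 2),       # divided twice before being left
            "GD2": (f"GD{n}.2", 0),
            "GGD": (f"GGD{n}.2", 0),      # wrong great-granddaughter
        }
    return _emit(truth, slot_map)


def generate_count_sample(model: str, params: dict, n: int, seed=None) -> np.ndarray:
    """I.i.d. count sample from a named distribution (front-end for the
    count-model tests).

    Models: ``poisson`` (lam), ``poisson_mixture`` (p, lam),
    ``negbin`` (mu, theta), ``gamma_poisson`` (mu, theta; explicit
    gamma-then-Poisson compounding, distributionally identical to negbin).
    """
    rng = np.random.default_rng(seed)
    n = int(n)
    if model == "poisson":
        lam = params["lam"]
        if lam <= 0:
            raise ValueError("lam must be positive")
        return rng.poisson(lam, size=n)
    if model == "poisson_mixture":
        p = np.asarray(params["p"], dtype=float)
        lam = np.asarray(params["lam"], dtype=float)
        if not np.isclose(p.sum(), 1.0) or np.any(lam <= 0):
            raise ValueError("weights must sum to 1 and rates be positive")
        comp = rng.choice(len(p), size=n, p=p)
        return rng.poisson(lam[comp])
    if model in ("negbin", "gamma_poisson"):
        mu, theta = params["mu"], params["theta"]
        if mu <= 0 or theta <= 0:
            raise ValueError("mu and theta must be positive")
        if model == "negbin":
            return rng.negative_binomial(theta, theta / (theta + mu), size=n)
        lam = rng.gamma(theta, mu / theta, size=n)
        return rng.poisson(lam)
    raise ValueError(f"unknown model {model!r}")
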