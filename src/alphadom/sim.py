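"""Forward-time simulator of tandem HOR arrays under concerted evolution.

The model has three forces, applied in a fixed order within each
generation:

1. **Sporadic mutation** — per copy, a Poisson(mu x unit_len) number of
   substitutions at uniform positions.
2. **Gene conversion** — Poisson(conv_rate) events; each overwrites a
   tract (geometric length) of a uniformly chosen acceptor copy with the
   homologous tract of a donor within ``xo_offset_max`` copies.
   Conversion is copy-number neutral and, because the donor haplotype is
   stamped onto a foreign background, it introduces divergence into the
   acceptor's domain rather than homogeneity.
3. **Unequal crossover** — Poisson(xo_rate) attempts between copy ``i``
   and copy ``i+d`` (``d`` uniform in [1, xo_offset_max]).  An attempt
   succeeds only if the two copies are near-identical
   (``identity >= xo_identity_min``): mitotic exchange requires repeats
   in close linear vicinity that have not yet diverged.  On success one
   reciprocal product — expansion or contraction by exactly ``d`` copies,
   fair coin — replaces the array, modelling transmission of a single
   chromatid lineage.  Products that would leave ``copy_bounds`` are
   rejected (and logged as such) rather than truncated, so every accepted
   crossover changes copy number by exactly +/- d.

Every event is logged; replaying the log against the initial array
reproduces the final array bit-exactly, which is the ground truth used
by the recovery tests throughout the package.

The module also provides *planted-structure* builders
(:func:`planted_domain_array`, :func:`archetype_array`) that write known
domains, barriers, duplicate pairs and conversion tracts directly into a
synthetic array so detection stages can be scored against exact truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import ParameterError
from .model import SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {c: i for i, c in enumerate("ACGT")}


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    out = np.empty(len(arr), dtype=np.uint8)
    for i, c in enumerate("ACGT"):
        out[arr == ord(c)] = i
    return out


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def copy_identity(a: np.ndarray, b: np.ndarray) -> float:
    """Ungapped identity between two equal-length encoded copies.

    Copies of unequal length (indel stress-tests) fall back to an
    edit-distance identity via edlib.
    """
    if len(a) == len(b):
        return float(np.mean(a == b))
    import edlib

    res = edlib.align(_decode(a), _decode(b), task="distance")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulation run.

    Defaults put the array in the regime the analysis stages are built
    for: unit-scale sporadic divergence of a few tenths of a percent and
    crossovers gated to near-identical, linearly close copies.
    """

    n0: int = 30
    unit_len: int = 652
    mu: float = 2e-5  # substitutions / bp / copy / generation
    conv_rate: float = 0.05  # conversion events / array / generation
    conv_tract_mean: float = 60.0  # bp, geometric
    xo_rate: float = 0.05  # crossover attempts / array / generation
    xo_identity_min: float = 0.98
    xo_offset_max: int = 4
    copy_bounds: tuple[int, int] = (5, 200)
    generations: int = 100
    seed: int = 0

    def validate(self) -> None:
        if min(self.mu, self.conv_rate, self.xo_rate) < 0:
            raise ParameterError("rates must be non-negative")
        if not (0 < self.xo_identity_min <= 1):
            raise ParameterError("xo_identity_min must be in (0, 1]")
        if not (self.copy_bounds[0] <= self.n0 <= self.copy_bounds[1]):
            raise ParameterError(
                f"n0={self.n0} outside copy_bounds {self.copy_bounds}"
            )
        if self.xo_offset_max < 1:
            raise ParameterError("xo_offset_max must be >= 1")


@dataclass
class SimArray:
    """An evolving tandem array: an ordered list of encoded unit copies."""

    copies: list[np.ndarray]
    generation: int = 0
    lineage: str = "L0"

    @property
    def n_copies(self) -> int:
        return len(self.copies)

    def to_strings(self) -> list[str]:
        return [_decode(c) for c in self.copies]

    def clone(self, lineage: Optional[str] = None) -> "SimArray":
        return SimArray(
            copies=[c.copy() for c in self.copies],
            generation=self.generation,
            lineage=lineage or self.lineage,
        )


# --- event records (replayable) -------------------------------------------


@dataclass(frozen=True)
class Mutation:
    generation: int
    copy: int
    pos: int
    base_from: int
    base_to: int


@dataclass(frozen=True)
class Conversion:
    generation: int
    donor: int
    acceptor: int
    start: int
    end: int


@dataclass(frozen=True)
class Crossover:
    generation: int
    i: int
    offset: int
    product: str  # "expansion" | "contraction"
    accepted: bool
    reject_reason: str = ""

    @property
    def size_change(self) -> int:
        if not self.accepted:
            return 0
        return self.offset if self.product == "expansion" else -self.offset


@dataclass
class EventLog:
    initial_copies: list[np.ndarray]
    events: list = field(default_factory=list)

    def counts(self) -> dict:
        out = {"mutation": 0, "conversion": 0, "crossover": 0, "rejected_crossover": 0}
        for e in self.events:
            if isinstance(e, Mutation):
                out["mutation"] += 1
            elif isinstance(e, Conversion):
                out["conversion"] += 1
            elif isinstance(e, Crossover):
                out["crossover" if e.accepted else "rejected_crossover"] += 1
        return out


def init_array(params: SimParams, ancestor: Optional[str] = None,
               rng: Optional[np.random.Generator] = None) -> SimArray:
    """Create n0 identical copies of a random (seeded) or supplied ancestor unit."""
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if ancestor is None:
        unit = rng.integers(0, 4, size=params.unit_len).astype(np.uint8)
    else:
        if len(ancestor) != params.unit_len:
            raise ParameterError(
                f"ancestor length {len(ancestor)} != unit_len {params.unit_len}"
            )
        unit = _encode(ancestor)
    return SimArray(copies=[unit.copy() for _ in range(params.n0)])


def step(array: SimArray, params: SimParams, rng: np.random.Generator) -> list:
    """Advance the array one generation in place; return the event list."""
    events: list = []
    gen = array.generation + 1
    copies = array.copies

    # 1. sporadic mutation
    for ci, cp in enumerate(copies):
        n_mut = rng.poisson(params.mu * len(cp))
        for _ in range(n_mut):
            pos = int(rng.integers(0, len(cp)))
            old = int(cp[pos])
            new = int((old + 1 + rng.integers(0, 3)) % 4)
            cp[pos] = new
            events.append(Mutation(gen, ci, pos, old, new))

    # 2. gene conversion (copy-number neutral)
    n_conv = rng.poisson(params.conv_rate)
    for _ in range(n_conv):
        n = len(copies)
        if n < 2:
            break
        acceptor = int(rng.integers(0, n))
        for _try in range(16):
            delta = int(rng.integers(1, params.xo_offset_max + 1))
            if rng.random() < 0.5:
                delta = -delta
            donor = acceptor + delta
            if 0 <= donor < n:
                break
        else:
            continue
        span = min(len(copies[donor]), len(copies[acceptor]))
        tract = int(rng.geometric(1.0 / params.conv_tract_mean))
        start = int(rng.integers(0, span))
        end = min(start + tract, span)
        copies[acceptor][start:end] = copies[donor][start:end]
        events.append(Conversion(gen, donor, acceptor, start, end))

    # 3. unequal crossover, gated on near-identity of the partners
    n_xo = rng.poisson(params.xo_rate)
    for _ in range(n_xo):
        n = len(copies)
        i = int(rng.integers(0, n))
        d = int(rng.integers(1, params.xo_offset_max + 1))
        product = "expansion" if rng.random() < 0.5 else "contraction"
        if i + d >= n:
            events.append(Crossover(gen, i, d, product, False, "out_of_range"))
            continue
        ident = copy_identity(copies[i], copies[i + d])
        if ident < params.xo_identity_min:
            events.append(Crossover(gen, i, d, product, False, "identity_gate"))
            continue
        new_n = n + d if product == "expansion" else n - d
        if not (params.copy_bounds[0] <= new_n <= params.copy_bounds[1]):
            events.append(Crossover(gen, i, d, product, False, "copy_bounds"))
            continue
        if product == "expansion":
            array.copies = copies = (
                copies[: i + d] + [c.copy() for c in copies[i:]]
            )
        else:
            array.copies = copies = copies[:i] + copies[i + d :]
        events.append(Crossover(gen, i, d, product, True))

    array.generation = gen
    return events


def evolve(array: SimArray, params: SimParams,
           rng: Optional[np.random.Generator] = None) -> tuple[SimArray, EventLog]:
    """Run ``params.generations`` steps; the returned log replays bit-exactly."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    log = EventLog(initial_copies=[c.copy() for c in array.copies])
    for _ in range(params.generations):
        log.events.extend(step(array, params, rng))
    return array, log


def simulate(params: SimParams, ancestor: Optional[str] = None
             ) -> tuple[SimArray, SimArray, EventLog]:
    """Convenience wrapper: init + evolve with one seeded generator."""
    rng = np.random.default_rng(params.seed)
    array = init_array(params, ancestor=ancestor, rng=rng)
    initial = array.clone()
    final, log = evolve(array, params, rng=rng)
    return initial, final, log


def replay(log: EventLog) -> list[np.ndarray]:
    """Apply the event log to its initial array; must reproduce the final state."""
    copies = [c.copy() for c in log.initial_copies]
    for e in log.events:
        if isinstance(e, Mutation):
            copies[e.copy][e.pos] = e.base_to
        elif isinstance(e, Conversion):
            copies[e.acceptor][e.start : e.end] = copies[e.donor][e.start : e.end]
        elif isinstance(e, Crossover) and e.accepted:
            if e.product == "expansion":
                copies = copies[: e.i + e.offset] + [c.copy() for c in copies[e.i :]]
            else:
                copies = copies[: e.i] + copies[e.i + e.offset :]
    return copies


def split_lineages(array: SimArray, params: SimParams, g_split: int
                   ) -> tuple[SimArray, SimArray]:
    """Duplicate the array and evolve the two lineages independently.

    Each lineage gets an independent substream spawned from the master
    seed, so the pair is reproducible from ``params.seed`` alone.
    """
    seeds = np.random.SeedSequence(params.seed).spawn(2)
    out = []
    for tag, ss in zip(("A", "B"), seeds):
        child = array.clone(lineage=f"{array.lineage}.{tag}")
        p = replace(params, generations=g_split)
        evolve(child, p, rng=np.random.default_rng(ss))
        out.append(child)
    return out[0], out[1]


def sample_clones(array: SimArray, n: int, window: Optional[tuple[int, int]] = None,
                  dup_prob: float = 0.0, seed: int = 0) -> list[SequenceRecord]:
    """Emulate PCR-clone sampling of a sub-window of the HOR.

    Copies are drawn uniformly with replacement; with probability
    ``dup_prob`` a draw re-uses the previous draw's template (a PCR
    duplicate).  Output ids carry no array position, mirroring the
    anonymity of cloned repeats.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    unit_min = min(len(c) for c in array.copies)
    if window is None:
        window = (0, unit_min)
    if window[1] - window[0] > unit_min or window[1] > unit_min or window[0] < 0:
        raise ParameterError(f"window {window} exceeds unit length {unit_min}")
    rng = np.random.default_rng(seed)
    out = []
    prev = None
    for j in range(n):
        if prev is not None and rng.random() < dup_prob:
            idx = prev
        else:
            idx = int(rng.integers(0, array.n_copies))
        prev = idx
        seq = _decode(array.copies[idx][window[0] : window[1]])
        out.append(SequenceRecord(id=f"clone_{j + 1:03d}", sequence=seq,
                                  source=f"simulated:{array.lineage}"))
    return out


# ---------------------------------------------------------------------------
# planted-structure builders: exact ground truth for the detection stages


def random_unit(rng: np.random.Generator, unit_len: int) -> np.ndarray:
    return rng.integers(0, 4, size=unit_len).astype(np.uint8)


def _mutate(unit: np.ndarray, rng: np.random.Generator, rate: float) -> np.ndarray:
    out = unit.copy()
    n = rng.binomial(len(out), rate)
    pos = rng.choice(len(out), size=n, replace=False)
    out[pos] = (out[pos] + 1 + rng.integers(0, 3, size=n)) % 4
    return out


CENPB_BOX_EXAMPLE = "ATTCGTTGGAAACGGGA"  # matches all 9 essential positions


def hor_ancestor(rng: np.random.Generator, k: int = 11, monomer_len: int = 171,
                 monomer_divergence: float = 0.08, site: str = "AAGCTT",
                 site_offset: int = 30, cenpb: bool = True) -> str:
    """Build a k-monomer HOR ancestor unit.

    The k monomer variants are derived from one random monomer at
    ``monomer_divergence`` pairwise spacing, a restriction site is
    planted once near the unit start, an intact CENP-B box is written
    into every even monomer, and all other occurrences of the site
    (including across the unit-to-unit junction) are scrubbed so an
    in-silico digest cuts exactly once per unit.
    """
    base = random_unit(rng, monomer_len)
    monomers = [_mutate(base, rng, monomer_divergence) for _ in range(k)]
    if cenpb:
        box = _encode(CENPB_BOX_EXAMPLE)
        for i in range(0, k, 2):
            monomers[i][100 : 100 + len(box)] = box
    unit = np.concatenate(monomers)
    site_arr = _encode(site)
    unit[site_offset : site_offset + len(site_arr)] = site_arr

    # scrub stray site occurrences, including junction-spanning ones
    def scrub(u: np.ndarray) -> np.ndarray:
        s = _decode(np.concatenate([u, u]))
        pos = 0
        while True:
            hit = s.find(site, pos)
            if hit < 0 or hit >= len(u):
                break
            if hit != site_offset:
                j = (hit + 2) % len(u)
                u[j] = (u[j] + 1) % 4
                s = _decode(np.concatenate([u, u]))
            pos = hit + 1
        return u

    return _decode(scrub(unit))


@dataclass
class PlantedTruth:
    """Ground truth written into a planted array."""

    ancestor: str
    domain_sizes: list[int]
    dvn_columns: dict[str, list[int]]  # domain label -> planted columns
    boundary: Optional[int] = None  # first copy index of second domain
    barrier: Optional[tuple[int, int]] = None
    duplicate_pair: Optional[tuple[int, int]] = None
    tracts: list[tuple[int, int, int]] = field(default_factory=list)
    # (copy index, first donor-DVN ordinal, n_dvns) for planted conversions
    sporadic_rate: float = 0.0


def _plant_dvn_set(rng: np.random.Generator, unit: np.ndarray, columns: np.ndarray
                   ) -> np.ndarray:
    """Return a haplotype: the unit with a fixed alternate base at each column."""
    hap = unit.copy()
    hap[columns] = (hap[columns] + 1 + rng.integers(0, 3, size=len(columns))) % 4
    return hap


def count_shared_variant_columns(copies: Sequence[np.ndarray], min_share: int = 2
                                 ) -> int:
    """Alignment-free truth count of DVN columns in equal-length copies.

    Consensus = column majority (ties A<C<G<T); a column counts when at
    least ``min_share`` copies share the identical non-consensus state.
    Used as the independent oracle for the pipeline's ``dvn_columns``.
    """
    mat = np.stack(copies)
    n_cols = 0
    for j in range(mat.shape[1]):
        vals, counts = np.unique(mat[:, j], return_counts=True)
        cons = vals[np.argmax(counts)]  # np.unique sorts, so ties break low
        if any(v != cons and c >= min_share for v, c in zip(vals, counts)):
            n_cols += 1
    return n_cols


def planted_domain_array(seed: int = 0, n_a: int = 20, n_b: int = 20,
                         n_dvns: int = 12, unit_len: int = 600,
                         sporadic: float = 0.002,
                         penetrance: Optional[tuple[float, float]] = None,
                         n_barrier: int = 0, barrier_divergence: float = 0.04,
                         duplicate_pair: bool = False,
                         tract_dvns: int = 0, tract_copies: Sequence[int] = (),
                         ancestor: Optional[str] = None
                         ) -> tuple[list[SequenceRecord], PlantedTruth]:
    """Two homogenisation domains with disjoint planted DVN sets.

    Layout along the array: ``n_a`` copies carrying DVN set A, an
    optional barrier of ``n_barrier`` heavily diverged copies (optionally
    containing an identical adjacent duplicate pair), then ``n_b`` copies
    carrying DVN set B.  With ``penetrance=None`` every domain member
    carries every domain DVN; a ``(lo, hi)`` range instead gives each DVN
    to a random contiguous sub-run covering that fraction of the domain,
    producing the subdomain structure real arrays show.
    ``tract_copies`` (indices into domain A) each additionally receive
    the first ``tract_dvns`` B-defining states — a planted conversion
    tract.  Sporadic noise is added independently per copy at
    ``sporadic`` substitutions/bp; the duplicate pair is copied *after*
    the noise, as the freshest event on the array, so its two copies are
    bit-identical.
    """
    rng = np.random.default_rng(seed)
    unit = _encode(ancestor) if ancestor is not None else random_unit(rng, unit_len)
    unit_len = len(unit)
    cols = rng.choice(unit_len, size=2 * n_dvns, replace=False)
    cols_a, cols_b = np.sort(cols[:n_dvns]), np.sort(cols[n_dvns:])
    hap_a = _plant_dvn_set(rng, unit, cols_a)
    hap_b = _plant_dvn_set(rng, unit, cols_b)

    def domain_copies(hap: np.ndarray, cols: np.ndarray, size: int
                      ) -> list[np.ndarray]:
        if penetrance is None:
            return [hap.copy() for _ in range(size)]
        out = [unit.copy() for _ in range(size)]
        for col in cols:
            lo, hi = penetrance
            run = max(2, int(round(size * rng.uniform(lo, hi))))
            run = min(run, size)
            start = int(rng.integers(0, size - run + 1))
            for c in out[start : start + run]:
                c[col] = hap[col]
        return out

    copies: list[np.ndarray] = domain_copies(hap_a, cols_a, n_a)
    barrier = None
    dup = None
    if n_barrier:
        start = len(copies)
        copies.extend(_mutate(unit, rng, barrier_divergence)
                      for _ in range(n_barrier))
        barrier = (start, start + n_barrier - 1)
        if duplicate_pair and n_barrier >= 2:
            mid = start + n_barrier // 2 - 1
            dup = (mid, mid + 1)
    boundary = len(copies)
    copies.extend(domain_copies(hap_b, cols_b, n_b))

    tracts = []
    for ci in tract_copies:
        t = min(tract_dvns, n_dvns)
        tcols = cols_b[:t]
        copies[ci][tcols] = hap_b[tcols]
        tracts.append((ci, 0, t))

    if sporadic > 0:
        copies = [_mutate(c, rng, sporadic) for c in copies]
    if dup is not None:
        copies[dup[1]] = copies[dup[0]].copy()

    records = [
        SequenceRecord(id=f"copy_{i + 1:03d}", sequence=_decode(c), source="planted")
        for i, c in enumerate(copies)
    ]
    truth = PlantedTruth(
        ancestor=_decode(unit),
        domain_sizes=[n_a, n_b],
        dvn_columns={"A": cols_a.tolist(), "B": cols_b.tolist()},
        boundary=boundary,
        barrier=barrier,
        duplicate_pair=dup,
        tracts=tracts,
        sporadic_rate=sporadic,
    )
    return records, truth


@dataclass
class ArchetypeTruth:
    sequence: str
    ancestor_unit: str
    k: int
    monomer_len: int
    unit_len: int
    core_start: int
    core_end: int
    n_core_units: int
    domains: list[tuple[int, int]]  # copy index ranges, inclusive
    barrier: tuple[int, int]
    duplicate_pair: tuple[int, int]
    planted_dvn_columns: int
    sporadic_rate: float
    site: str


def archetype_array(seed: int = 0, n_domain1: int = 30, n_barrier: int = 5,
                    n_domain2: int = 20, k: int = 11, monomer_len: int = 171,
                    n_dvns: int = 60, n_barrier_dvns: int = 8,
                    penetrance: tuple[float, float] = (0.3, 0.9),
                    sporadic: float = 0.005,
                    n_flank_units: int = 3, flank_divergence: float = 0.12,
                    site: str = "AAGCTT") -> ArchetypeTruth:
    """Synthesise a D1Z5-like array: homogeneous HOR core with divergent flanks.

    The core is ``n_domain1 + n_barrier + n_domain2`` copies of a
    k-monomer HOR unit.  Each of the two large domains draws ``n_dvns``
    DVN columns, each carried by a random contiguous sub-run of the
    domain (``penetrance`` gives the run-length fraction range) —
    the subdomain structure left by successive homogenisation runs.  The
    intervening barrier copies carry their own DVN set over extra
    background divergence, so they are distant from both flanks, and
    contain one adjacent pair duplicated as the freshest event on the
    array (bit-identical, the product of one unequal crossover).
    Divergent units and a partial unit flank the core on both sides.
    """
    rng = np.random.default_rng(seed)
    unit_len = k * monomer_len
    ancestor = hor_ancestor(rng, k=k, monomer_len=monomer_len, site=site)
    unit = _encode(ancestor)

    n_core = n_domain1 + n_barrier + n_domain2
    all_cols = rng.choice(unit_len, size=2 * n_dvns + n_barrier_dvns, replace=False)
    cols_1 = np.sort(all_cols[:n_dvns])
    cols_2 = np.sort(all_cols[n_dvns : 2 * n_dvns])
    cols_bar = np.sort(all_cols[2 * n_dvns :])

    hap1 = _plant_dvn_set(rng, unit, cols_1)
    hap2 = _plant_dvn_set(rng, unit, cols_2)
    # barrier haplotype: its own DVNs on top of extra background divergence,
    # so it is distant from both flanking domains
    hap_bar = _plant_dvn_set(rng, _mutate(unit, rng, 0.02), cols_bar)

    # every DVN must stay a minority state of the 55-copy core, or the
    # column consensus would flip onto the variant
    max_carriers = (n_core - 1) // 2

    def domain_copies(hap: np.ndarray, cols: np.ndarray, size: int
                      ) -> list[np.ndarray]:
        out = [unit.copy() for _ in range(size)]
        for col in cols:
            run = max(2, int(round(size * rng.uniform(*penetrance))))
            run = min(run, size, max_carriers)
            # homogenisation runs are bounded by the barrier, so half of
            # them terminate exactly at a domain edge
            u = rng.random()
            if u < 0.25:
                start = 0
            elif u < 0.5:
                start = size - run
            else:
                start = int(rng.integers(0, size - run + 1))
            for c in out[start : start + run]:
                c[col] = hap[col]
        return out

    copies = domain_copies(hap1, cols_1, n_domain1)
    copies.extend(_mutate(hap_bar, rng, 0.004) for _ in range(n_barrier))
    copies.extend(domain_copies(hap2, cols_2, n_domain2))
    copies = [_mutate(c, rng, sporadic) for c in copies]
    # the duplicate pair is the youngest event: copied after all noise
    mid = n_domain1 + n_barrier // 2 - 1
    copies[mid + 1] = copies[mid].copy()
    dup_pair = (mid, mid + 1)

    flank_left = [_mutate(unit, rng, flank_divergence) for _ in range(n_flank_units)]
    flank_right = [_mutate(unit, rng, flank_divergence) for _ in range(n_flank_units)]
    partial_left = _mutate(unit, rng, flank_divergence)[-5 * monomer_len :]
    partial_right = _mutate(unit, rng, flank_divergence)[: 7 * monomer_len]

    parts = [partial_left] + flank_left + copies + flank_right + [partial_right]
    seq = _decode(np.concatenate(parts))
    core_start = len(partial_left) + n_flank_units * unit_len
    core_end = core_start + n_core * unit_len

    planted_cols = count_shared_variant_columns(copies)
    return ArchetypeTruth(
        sequence=seq,
        ancestor_unit=ancestor,
        k=k,
        monomer_len=monomer_len,
        unit_len=unit_len,
        core_start=core_start,
        core_end=core_end,
        n_core_units=n_core,
        domains=[(0, n_domain1 - 1), (n_domain1 + n_barrier, n_core - 1)],
        barrier=(n_domain1, n_domain1 + n_barrier - 1),
        duplicate_pair=dup_pair,
        planted_dvn_columns=planted_cols,
        sporadic_rate=sporadic,
        site=site,
    )
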