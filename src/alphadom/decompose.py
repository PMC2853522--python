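"""Decomposition of a raw alpha-satellite array into monomers and HOR units.

The stages mirror how a long assembled array is characterised: derive
(or accept) a ~171-bp monomer consensus, tile the array with it, find
the higher-order period k from the lag at which monomers are most
similar, phase the tiling into k-monomer units (anchored either on a
restriction site or on maximum unit-to-unit homogeneity), and extract
the homogeneous core where unit-to-consensus identity is high.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np

from .errors import (
    AnchoringError,
    DecompositionError,
    EmptyCoreError,
    NoHorStructureError,
    ParameterError,
)
from .model import HORPhasing, HORUnit, MonomerCall, SequenceRecord

MONOMER_LEN = 171


def _to_seq(array: Union[SequenceRecord, str]) -> str:
    return array.sequence if isinstance(array, SequenceRecord) else array


def _bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def derive_monomer_consensus(seq: str, lag_range: tuple[int, int] = (150, 200)
                             ) -> str:
    """Self-derive the monomer consensus from the array's own periodicity.

    The monomer period is the lag in ``lag_range`` maximising the
    match fraction between the array and its own shift; the consensus is
    then the column majority over the implied phase frames.
    """
    b = _bytes(seq)
    lo, hi = lag_range
    if len(b) < 2 * hi:
        raise DecompositionError("array too short to self-derive a monomer consensus")
    best_lag, best_score = lo, -1.0
    for lag in range(lo, hi + 1):
        score = float(np.mean(b[:-lag] == b[lag:]))
        if score > best_score:
            best_lag, best_score = lag, score
    n_frames = len(b) // best_lag
    if n_frames < 5:
        raise DecompositionError("fewer than 5 monomer frames; cannot self-derive")
    frames = b[: n_frames * best_lag].reshape(n_frames, best_lag)
    cons = np.empty(best_lag, dtype=np.uint8)
    for j in range(best_lag):
        vals, counts = np.unique(frames[:, j], return_counts=True)
        cons[j] = vals[np.argmax(counts)]
    return cons.tobytes().decode()


def detect_monomers(array: Union[SequenceRecord, str],
                    monomer_consensus: Optional[str] = None,
                    min_identity: float = 0.60,
                    jitter: int = 15) -> list[MonomerCall]:
    """Greedy left-to-right tiling of the array by monomer-consensus matches.

    Each call is the best-identity placement of the consensus within
    ``jitter`` bp of the expected next start (ties to the smaller
    start); placements below ``min_identity`` leave an unassigned gap of
    one monomer length instead of a call.
    """
    seq = _to_seq(array)
    b = _bytes(seq)
    if monomer_consensus is None:
        monomer_consensus = derive_monomer_consensus(seq)
    cons = _bytes(monomer_consensus)
    L = len(cons)
    if len(b) < 2 * L:
        raise DecompositionError("array shorter than two monomer lengths")

    calls: list[MonomerCall] = []
    # phase the first call by scanning one full period
    expected = _best_start(b, cons, 0, L + jitter)[0]
    index = 0
    while expected + L <= len(b):
        lo = max(0, expected - jitter)
        if calls:
            lo = max(lo, calls[-1].end)  # calls must not overlap
        hi = min(expected + jitter, len(b) - L)
        if hi < lo:
            break
        start, ident = _best_start(b, cons, lo, hi + 1)
        if ident >= min_identity:
            calls.append(MonomerCall(start=start, end=start + L,
                                     identity_to_consensus=ident, index=index))
            index += 1
            expected = start + L
        else:
            expected += L
    if not calls:
        raise DecompositionError("no monomer-scale periodic signal above min_identity")
    return calls


def _best_start(b: np.ndarray, cons: np.ndarray, lo: int, hi: int
                ) -> tuple[int, float]:
    L = len(cons)
    best_s, best_i = lo, -1.0
    for s in range(lo, hi):
        if s + L > len(b):
            break
        ident = float(np.mean(b[s : s + L] == cons))
        if ident > best_i:
            best_s, best_i = s, ident
    return best_s, best_i


def unassigned_intervals(calls: Sequence[MonomerCall], array_len: int
                         ) -> list[tuple[int, int]]:
    """Gaps not covered by monomer calls; together with the calls these
    exactly partition [0, array_len)."""
    out = []
    pos = 0
    for c in calls:
        if c.start > pos:
            out.append((pos, c.start))
        pos = c.end
    if pos < array_len:
        out.append((pos, array_len))
    return out


def _monomer_matrix(calls: Sequence[MonomerCall], seq: str) -> np.ndarray:
    b = _bytes(seq)
    L = min(c.length for c in calls)
    return np.stack([b[c.start : c.start + L] for c in calls])


def infer_hor_period(monomers: Sequence[MonomerCall],
                     array: Union[SequenceRecord, str],
                     k_max: int = 30,
                     flat_margin: float = 0.02,
                     tie_margin: float = 0.005) -> tuple[int, dict[int, float]]:
    """Find the HOR period k as the monomer lag of maximum mean identity.

    Returns ``(k, profile)`` where ``profile`` maps each candidate lag to
    the mean identity between monomers i and i+lag.  A flat profile
    (max - median < ``flat_margin``) means there is no higher-order
    structure above the monomer period; among lags within ``tie_margin``
    of the maximum the smallest wins, so the fundamental period beats its
    multiples.
    """
    seq = _to_seq(array)
    n = len(monomers)
    if n < 6:
        raise NoHorStructureError("too few monomers to test higher-order periodicity")
    mat = _monomer_matrix(monomers, seq)
    k_hi = min(k_max, n // 3)
    if k_hi < 2:
        raise NoHorStructureError("too few monomers for any candidate period")
    profile: dict[int, float] = {}
    for k in range(2, k_hi + 1):
        profile[k] = float(np.mean(mat[:-k] == mat[k:]))
    values = np.array(list(profile.values()))
    if values.max() - np.median(values) < flat_margin:
        raise NoHorStructureError(
            "lag-identity profile is flat: no HOR structure above the monomer period"
        )
    best = values.max()
    k = min(lag for lag, v in profile.items() if v >= best - tie_margin)
    return k, profile


def _contiguous(calls: Sequence[MonomerCall], first: int, last: int) -> bool:
    return all(calls[i].end == calls[i + 1].start for i in range(first, last))


def phase_hors(monomers: Sequence[MonomerCall],
               array: Union[SequenceRecord, str],
               k: int,
               anchor: Union[str, tuple[str, str]] = "max_homogeneity"
               ) -> HORPhasing:
    """Cut the monomer tiling into k-monomer HOR units at a chosen phase.

    ``anchor`` is ``"max_homogeneity"`` (pick the phase offset
    maximising mean unit-to-unit identity), ``("restriction_site",
    site)`` (unit starts at the monomer containing the site's first
    base), or ``("offset", o)`` for an explicit phase.  Leading/trailing
    partial units are kept, flagged ``complete=False``.
    """
    if k < 2:
        raise ParameterError("k must be >= 2")
    seq = _to_seq(array)
    n = len(monomers)
    if isinstance(anchor, tuple) and anchor[0] == "restriction_site":
        offset = _site_offset(monomers, seq, k, anchor[1])
    elif isinstance(anchor, tuple) and anchor[0] == "offset":
        offset = int(anchor[1])
        if not (0 <= offset < k):
            raise ParameterError(f"offset {offset} outside [0, {k})")
    elif anchor == "max_homogeneity":
        offset = _best_offset(monomers, seq, k)
    else:
        raise ParameterError(f"unknown anchor {anchor!r}")

    units: list[HORUnit] = []
    idx = 0
    if offset > 0:
        units.append(HORUnit(start=monomers[0].start, end=monomers[offset - 1].end,
                             monomer_span=(0, offset - 1), complete=False, index=idx))
        idx += 1
    first = offset
    while first + k <= n:
        last = first + k - 1
        complete = _contiguous(monomers, first, last)
        units.append(HORUnit(start=monomers[first].start, end=monomers[last].end,
                             monomer_span=(first, last), complete=complete, index=idx))
        idx += 1
        first += k
    if first < n:
        units.append(HORUnit(start=monomers[first].start, end=monomers[n - 1].end,
                             monomer_span=(first, n - 1), complete=False, index=idx))

    units = _with_identities(units, seq)
    return HORPhasing(k=k, anchor_offset=offset, units=units)


def _unit_matrix(units: Sequence[HORUnit], seq: str) -> np.ndarray:
    b = _bytes(seq)
    L = min(u.length for u in units)
    return np.stack([b[u.start : u.start + L] for u in units])


def _best_offset(monomers: Sequence[MonomerCall], seq: str, k: int) -> int:
    n = len(monomers)
    best_o, best_score = 0, -1.0
    for o in range(k):
        spans = [(monomers[f].start, monomers[f + k - 1].end)
                 for f in range(o, n - k + 1, k)]
        if len(spans) < 2:
            continue
        b = _bytes(seq)
        L = min(e - s for s, e in spans)
        mat = np.stack([b[s : s + L] for s, _ in spans])
        m = len(mat)
        score = 0.0
        pairs = 0
        for i in range(m):
            eq = mat[i + 1 :] == mat[i]
            score += float(eq.mean(axis=1).sum())
            pairs += m - i - 1
        score /= pairs
        if score > best_score:
            best_o, best_score = o, score
    if best_score < 0:
        raise ParameterError("not enough monomers for any complete unit")
    return best_o


def _site_offset(monomers: Sequence[MonomerCall], seq: str, k: int, site: str) -> int:
    hits = _find_all(seq, site)
    if not hits:
        raise AnchoringError(f"site {site} absent from array; try max_homogeneity")
    # monomer index containing each hit's first base
    starts = np.array([m.start for m in monomers])
    ends = np.array([m.end for m in monomers])
    hit_monomers = []
    for h in hits:
        j = np.searchsorted(ends, h, side="right")
        if j < len(monomers) and starts[j] <= h < ends[j]:
            hit_monomers.append(j)
    if not hit_monomers:
        raise AnchoringError(f"site {site} falls outside the monomer tiling")
    offsets, counts = np.unique(np.array(hit_monomers) % k, return_counts=True)
    offset = int(offsets[np.argmax(counts)])
    n_units = max(1, (len(monomers) - offset) // k)
    if counts.max() / n_units < 0.5:
        raise AnchoringError(
            f"site {site} present in fewer than half of candidate units; "
            "use max_homogeneity anchoring"
        )
    return offset


def _with_identities(units: list[HORUnit], seq: str) -> list[HORUnit]:
    """Attach mean identity of each complete unit to the unit consensus."""
    complete = [u for u in units if u.complete]
    if len(complete) < 2:
        return units
    mat = _unit_matrix(complete, seq)
    cons = np.empty(mat.shape[1], dtype=np.uint8)
    for j in range(mat.shape[1]):
        vals, counts = np.unique(mat[:, j], return_counts=True)
        cons[j] = vals[np.argmax(counts)]
    idents = (mat == cons).mean(axis=1)
    out = []
    it = iter(idents)
    for u in units:
        if u.complete:
            out.append(HORUnit(u.start, u.end, u.monomer_span, True,
                               float(next(it)), u.index))
        else:
            out.append(u)
    return out


def _find_all(seq: str, site: str) -> list[int]:
    out, pos = [], 0
    while True:
        hit = seq.find(site, pos)
        if hit < 0:
            return out
        out.append(hit)
        pos = hit + 1


_COMP = str.maketrans("ACGTN", "TGCAN")


def digest_insilico(array: Union[SequenceRecord, str], site: str) -> list[int]:
    """Fragment lengths of an in-silico restriction digest.

    Cuts at every occurrence of ``site`` on the forward strand; for a
    non-palindromic site, occurrences of its reverse complement are cut
    as well.  With no sites the whole array is one fragment.
    """
    if len(site) < 4:
        raise ParameterError("restriction site must be >= 4 bp")
    seq = _to_seq(array)
    site = site.upper()
    cuts = set(_find_all(seq, site))
    rc = site.translate(_COMP)[::-1]
    if rc != site:
        cuts.update(_find_all(seq, rc))
    if not cuts:
        return [len(seq)]
    edges = [0] + sorted(cuts) + [len(seq)]
    return [b - a for a, b in zip(edges, edges[1:]) if b > a]


def extract_core(phasing: HORPhasing, max_divergence: float = 0.05
                 ) -> list[HORUnit]:
    """Longest contiguous run of complete units within the divergence cap.

    A unit passes when its identity to the unit consensus is at least
    ``1 - max_divergence``; the homogeneous core is the longest run of
    consecutive passing complete units (first run wins ties).
    """
    complete = phasing.complete_units
    passing = [u is not None and u.mean_identity is not None
               and u.mean_identity >= 1.0 - max_divergence for u in complete]
    best_run: tuple[int, int] | None = None
    start = None
    for i, ok in enumerate(passing + [False]):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            if best_run is None or i - start > best_run[1] - best_run[0]:
                best_run = (start, i)
            start = None
    if best_run is None:
        raise EmptyCoreError("no complete unit within the divergence cap")
    return complete[best_run[0] : best_run[1]]
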