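"""Consensus-anchored alignment, variant calling and DVN classification.

Near-identical HOR copies are each aligned globally to a single
consensus and projected onto its columns, giving one fixed coordinate
system for the whole copy set without an O(n^2) multiple alignment.
Variants are per-copy deviations from the consensus state; a Diagnostic
Variant Nucleotide (DVN) is an alternate state shared identically by at
least two copies, and everything else is a sporadic mutation.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Optional, Sequence, Union

import numpy as np
from Bio import Align

from .errors import (
    EmptyInputError,
    OutlierCopyError,
    ParameterError,
    UndefinedRateError,
    ValidationError,
)
from .model import (
    ArrayAlignment,
    CenpBBoxCall,
    Consensus,
    DVNGroup,
    SequenceRecord,
    Variant,
    VariantPartition,
    STATE_ORDER,
)

#: affine-gap scoring for copy-to-consensus alignment (configurable deviation
#: from the unrecorded settings of the original ClustalW-based analyses)
DEFAULT_SCORING = {"match": 1.0, "mismatch": -1.0, "gap_open": -4.0, "gap_extend": -1.0}

#: equal-length copies at or above this ungapped identity skip the gapped DP;
#: at >=90% identity an affine-gap alignment of equal-length sequences cannot
#: beat the ungapped one under the default scoring
FAST_PATH_IDENTITY = 0.90


def _as_strings(copies) -> tuple[list[str], list[str]]:
    ids, seqs = [], []
    for i, c in enumerate(copies):
        if isinstance(c, SequenceRecord):
            ids.append(c.id)
            seqs.append(c.sequence)
        else:
            ids.append(f"copy_{i + 1:03d}")
            seqs.append(str(c).upper())
    return ids, seqs


def _majority(column: np.ndarray) -> tuple[str, float]:
    states, counts = np.unique(column, return_counts=True)
    best = counts.max()
    winners = {s for s, c in zip(states, counts) if c == best}
    for s in STATE_ORDER:
        if s in winners:
            return s, best / len(column)
    return sorted(winners)[0], best / len(column)


def build_consensus(copies, max_rounds: int = 4) -> Consensus:
    """Column-majority consensus of a copy collection.

    Equal-length copies are read as columns directly.  Ragged copies are
    consensus-anchored iteratively: a modal-length draft seeds the
    alignment, the majority is taken, and the cycle repeats until the
    consensus is stable (at most ``max_rounds``).  Gap-majority columns
    are removed so the consensus is plain DNA; ties break A<C<G<T<-.
    """
    ids, seqs = _as_strings(copies)
    if len(seqs) < 2:
        raise EmptyInputError("consensus requires at least 2 copies")
    lengths = {len(s) for s in seqs}
    if len(lengths) == 1:
        matrix = np.array([list(s) for s in seqs], dtype="<U1")
        return _consensus_of_matrix(matrix)
    # ragged: iterate consensus-anchored alignment from a modal-length draft
    mode_len = max(lengths, key=lambda L: sum(len(s) == L for s in seqs))
    draft = next(s for s in seqs if len(s) == mode_len)
    cons = Consensus(sequence=draft, support=np.ones(len(draft)))
    for _ in range(max_rounds):
        aln = _project_all(ids, seqs, cons.sequence)
        new = _consensus_of_matrix(aln.matrix)
        if new.sequence == cons.sequence:
            return new
        cons = new
    return cons


def _consensus_of_matrix(matrix: np.ndarray) -> Consensus:
    states, support = [], []
    for j in range(matrix.shape[1]):
        s, f = _majority(matrix[:, j])
        if s == "-":
            continue  # gap-majority columns leave consensus coordinates
        states.append(s)
        support.append(f)
    return Consensus(sequence="".join(states), support=np.array(support))


def _make_aligner(scoring: dict) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring["match"]
    aligner.mismatch_score = scoring["mismatch"]
    aligner.open_gap_score = scoring["gap_open"]
    aligner.extend_gap_score = scoring["gap_extend"]
    return aligner


def _project_one(cons: str, seq: str, aligner: Align.PairwiseAligner
                 ) -> tuple[np.ndarray, list[tuple[int, str]], float]:
    """Align one copy to the consensus; return (per-column states,
    insertions as (column, string), identity)."""
    cb = np.frombuffer(cons.encode(), dtype=np.uint8)
    sb = np.frombuffer(seq.encode(), dtype=np.uint8)
    if len(seq) == len(cons):
        ident = float(np.mean(cb == sb))
        if ident >= FAST_PATH_IDENTITY:
            return np.array(list(seq), dtype="<U1"), [], ident
    aln = aligner.align(cons, seq)[0]
    row = np.full(len(cons), "-", dtype="<U1")
    insertions: list[tuple[int, str]] = []
    blocks_c, blocks_s = aln.aligned
    prev_c = prev_s = 0
    matches = 0
    for (cs, ce), (ss, se) in zip(blocks_c, blocks_s):
        if ss > prev_s:  # copy bases skipped in consensus -> insertion
            insertions.append((prev_c, seq[prev_s:ss]))
        block = np.array(list(seq[ss:se]), dtype="<U1")
        row[cs:ce] = block
        matches += int(np.sum(cb[cs:ce] == sb[ss:se]))
        prev_c, prev_s = ce, se
    if prev_s < len(seq):
        insertions.append((prev_c, seq[prev_s:]))
    ident = matches / max(len(cons), len(seq))
    return row, insertions, ident


def _project_all(ids: list[str], seqs: list[str], cons: str,
                 scoring: Optional[dict] = None,
                 min_identity: Optional[float] = None) -> ArrayAlignment:
    aligner = _make_aligner(scoring or DEFAULT_SCORING)
    rows, all_ins = [], []
    for cid, s in zip(ids, seqs):
        row, ins, ident = _project_one(cons, s, aligner)
        if min_identity is not None and ident < min_identity:
            raise OutlierCopyError(
                f"copy {cid} aligns to the consensus at {ident:.1%} identity "
                f"(< {min_identity:.0%})"
            )
        rows.append(row)
        all_ins.extend((cid, col, istr) for col, istr in ins)
    return ArrayAlignment(copy_ids=list(ids), matrix=np.stack(rows),
                          consensus=cons, insertions=all_ins)


def anchor_align(copies, consensus: Optional[Consensus] = None,
                 scoring: Optional[dict] = None,
                 min_identity: float = 0.60,
                 max_length_ratio: float = 0.20) -> ArrayAlignment:
    """Project every copy onto the consensus coordinate system.

    Each copy is globally aligned to the consensus with affine gaps and
    its states written into the consensus columns; copy bases opposite
    consensus gaps become insertion records.  The consensus is
    re-estimated once from the projected matrix and, if it changed, all
    copies are realigned to the updated consensus.
    """
    ids, seqs = _as_strings(copies)
    if not seqs:
        raise EmptyInputError("no copies to align")
    if consensus is None:
        consensus = build_consensus(copies)
    for cid, s in zip(ids, seqs):
        if abs(len(s) - len(consensus)) > max_length_ratio * len(consensus):
            raise ValidationError(
                f"copy {cid} length {len(s)} departs more than "
                f"{max_length_ratio:.0%} from consensus length {len(consensus)}"
            )
    aln = _project_all(ids, seqs, consensus.sequence, scoring, min_identity)
    re_cons = _consensus_of_matrix(aln.matrix)
    if re_cons.sequence != consensus.sequence:
        aln = _project_all(ids, seqs, re_cons.sequence, scoring, min_identity)
    return aln


def copies_with_n(alignment: ArrayAlignment) -> list[str]:
    """Ids of copies containing ``N`` — excluded from variant calling but
    never silently dropped from the alignment itself."""
    return [cid for i, cid in enumerate(alignment.copy_ids)
            if np.any(alignment.matrix[i] == "N")]


def call_variants(alignment: ArrayAlignment) -> list[Variant]:
    """One variant per (copy, column) whose state differs from the consensus.

    Insertions are carried on the alignment object, not in the variant
    list, so the consensus coordinate system stays fixed.  Copies
    containing ``N`` anywhere are excluded (their ids are recoverable by
    comparing against ``alignment.copy_ids``); an ambiguous base is not
    evidence for or against a variant.
    """
    if alignment.n_copies == 0:
        raise EmptyInputError("empty alignment")
    cons = np.array(list(alignment.consensus), dtype="<U1")
    out: list[Variant] = []
    for i, cid in enumerate(alignment.copy_ids):
        row = alignment.matrix[i]
        if np.any(row == "N"):
            continue
        for j in np.nonzero(row != cons)[0]:
            out.append(Variant(copy_id=cid, column=int(j), alt_state=str(row[j])))
    return out


def classify_dvns(variants: Sequence[Variant], min_share: int = 2
                  ) -> VariantPartition:
    """Split variants into DVNs (shared by >= min_share copies) and sporadics.

    Sharing means the identical alternate state at the identical
    consensus column; two different alternate states at one column form
    (up to) two separate DVN groups.
    """
    if min_share < 2:
        raise ParameterError("min_share must be >= 2 (a singleton cannot be diagnostic)")
    groups: dict[tuple[int, str], set[str]] = defaultdict(set)
    for v in variants:
        groups[(v.column, v.alt_state)].add(v.copy_id)
    dvns, sporadic = [], []
    for (col, state), carriers in sorted(groups.items()):
        if len(carriers) >= min_share:
            dvns.append(DVNGroup(column=col, alt_state=state, carriers=frozenset(carriers)))
        else:
            sporadic.extend(Variant(cid, col, state) for cid in sorted(carriers))
    return VariantPartition(dvns=dvns, sporadic=sporadic)


def sporadic_rate(partition: VariantPartition, alignment: ArrayAlignment
                  ) -> tuple[float, dict[str, float]]:
    """Sporadic mutations as a percentage of all aligned cells.

    Returns ``(overall_percent, per_copy_percent)``; the per-copy rates
    expose heterogeneity that the single average hides.
    """
    if alignment.n_copies == 0 or alignment.n_columns == 0:
        raise UndefinedRateError("rate undefined on an empty alignment")
    n_cells = alignment.n_copies * alignment.n_columns
    overall = 100.0 * len(partition.sporadic) / n_cells
    per_copy = {cid: 0.0 for cid in alignment.copy_ids}
    for v in partition.sporadic:
        per_copy[v.copy_id] += 100.0 / alignment.n_columns
    return overall, per_copy


# ---------------------------------------------------------------------------
# CENP-B box scan

#: 17-bp degenerate CENP-B box consensus; the 9 non-N positions are the
#: nucleotides essential for CENP-B binding
CENPB_CONSENSUS = "NTTCGNNNNANNCGGGN"
CENPB_ESSENTIAL = tuple(i for i, c in enumerate(CENPB_CONSENSUS) if c != "N")
PRESENCE_FLOOR = 5  # a best hit at or below 5/9 is reported as box-absent


def scan_cenpb(monomers) -> list[CenpBBoxCall]:
    """Best CENP-B box match per monomer, scored on the 9 essential positions.

    The box is intact only when all nine essential nucleotides match;
    monomers whose best window scores no better than 5/9 are flagged
    absent.  Monomers are scanned in the given orientation only.
    """
    _, seqs = _as_strings(monomers)
    ess_chars = np.array([CENPB_CONSENSUS[i] for i in CENPB_ESSENTIAL], dtype="<U1")
    width = len(CENPB_CONSENSUS)
    out = []
    for mi, seq in enumerate(seqs):
        if len(seq) < width:
            raise ValidationError(f"monomer {mi} shorter than the CENP-B box")
        arr = np.array(list(seq), dtype="<U1")
        best_off, best_n = 0, -1
        for off in range(len(seq) - width + 1):
            n = int(np.sum(arr[np.array(CENPB_ESSENTIAL) + off] == ess_chars))
            if n > best_n:
                best_off, best_n = off, n
        out.append(CenpBBoxCall(monomer_index=mi, offset=best_off,
                                n_essential_matches=best_n,
                                intact=best_n == len(CENPB_ESSENTIAL),
                                present=best_n > PRESENCE_FLOOR))
    return out
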