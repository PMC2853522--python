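"""Domain segmentation, event inference and repeat-set comparison.

Each array copy is reduced to its DVN haplotype (the binary vector of
DVN groups it carries).  Homogenisation domains — contiguous runs of
copies homogenised onto a common haplotype by accumulated unequal
crossovers — are found by adjacency-constrained agglomerative merging on
Jaccard similarity.  On top of the domain map the module infers the
molecular events that shaped it: barriers (short runs alien to both
flanking domains), duplicate pairs (adjacent near-identical copies, the
fresh product of one unequal crossover) and conversion tracts (runs of
foreign-domain DVNs stamped onto a copy).  Unordered repeat sets
(PCR clones of unknown array position) cannot be segmented; for those
the supported path is clustering-based set comparison, including a
nearest-neighbour intermingling statistic calibrated by permutation.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

from .errors import EmptyInputError, OrderingRequiredError, ParameterError
from .model import (
    ArrayAlignment,
    ConversionTract,
    Domain,
    DomainMap,
    DuplicatePair,
    DVNGroup,
    HaplotypeMatrix,
    SetComparison,
    VariantPartition,
)


def haplotype_matrix(partition: VariantPartition, copy_order: Sequence[str],
                     ordered: bool = True) -> HaplotypeMatrix:
    """Binary copies x DVN-groups carrier matrix in the given copy order.

    Copies carrying no DVN at all are kept as all-zero rows; such copies
    are real (and common in young, homogeneous arrays) and must stay
    visible to segmentation.
    """
    groups = list(partition.dvns)
    mat = np.zeros((len(copy_order), len(groups)), dtype=np.int8)
    index = {cid: i for i, cid in enumerate(copy_order)}
    for g_idx, g in enumerate(groups):
        for cid in g.carriers:
            if cid in index:
                mat[index[cid], g_idx] = 1
    return HaplotypeMatrix(copy_ids=list(copy_order), matrix=mat,
                           dvns=groups, ordered=ordered)


def _jaccard_matrix(mat: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard similarity of binary rows; all-zero rows have
    similarity 0 to everything (including each other)."""
    inter = (mat @ mat.T).astype(float)
    sizes = mat.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)
    return sim


def segment_domains(hm: HaplotypeMatrix, tau: float = 0.2,
                    min_domain_size: int = 2) -> DomainMap:
    """Adjacency-constrained agglomerative segmentation of the copy order.

    Starting from singleton segments, the adjacent pair with the highest
    mean inter-segment Jaccard similarity is merged until the best merge
    falls below ``tau``.  Final segments of at least ``min_domain_size``
    copies become domains, with defining DVN set = groups carried by at
    least half of the members; smaller segments are left unassigned
    (barrier candidates for :func:`detect_barriers`).
    """
    if not hm.ordered:
        raise OrderingRequiredError(
            "segmentation needs array-positioned copies; use compare_sets "
            "for unordered clone sets"
        )
    n = hm.n_copies
    if n == 0:
        raise EmptyInputError("empty haplotype matrix")
    sim = _jaccard_matrix(hm.matrix)
    segments: list[list[int]] = [[i] for i in range(n)]

    def merge_score(a: list[int], b: list[int]) -> float:
        return float(sim[np.ix_(a, b)].mean())

    while len(segments) > 1:
        scores = [merge_score(segments[i], segments[i + 1])
                  for i in range(len(segments) - 1)]
        best = int(np.argmax(scores))
        if scores[best] < tau:
            break
        segments[best] = segments[best] + segments[best + 1]
        del segments[best + 1]

    domains, unassigned = [], []
    for seg in segments:
        if len(seg) >= min_domain_size:
            members = hm.matrix[seg]
            defining = frozenset(
                int(g) for g in np.nonzero(members.mean(axis=0) >= 0.5)[0]
            )
            domains.append(Domain(first_copy=seg[0], last_copy=seg[-1],
                                  defining_dvns=defining))
        else:
            unassigned.extend(seg)
    return DomainMap(domains=domains, barriers=[], unassigned=sorted(unassigned),
                     n_copies=n)


def detect_barriers(dmap: DomainMap, hm: HaplotypeMatrix, beta: float = 0.05,
                    max_barrier_size: int = 5
                    ) -> tuple[DomainMap, list[dict]]:
    """Label inter-domain copy runs alien to both flanks as barriers.

    Candidate runs are the copies between consecutive major domains
    (unassigned copies and whole domains of at most ``max_barrier_size``
    copies).  A run whose mean Jaccard similarity to both flanking major
    domains is below ``beta`` becomes a barrier; the returned report
    also carries the cross-similarity between the flanking domains
    themselves, which a true barrier keeps near zero.
    """
    if len(dmap.domains) < 2:
        return dmap, []
    sim = _jaccard_matrix(hm.matrix)
    major = [d for d in dmap.domains if d.size > max_barrier_size]
    if len(major) < 2:
        return dmap, []
    new_domains = list(major)
    barriers = list(dmap.barriers)
    unassigned = set(dmap.unassigned)
    report = []
    for left, right in zip(major, major[1:]):
        run = [c for c in range(left.last_copy + 1, right.first_copy)]
        if not run:
            continue
        left_members = list(range(left.first_copy, left.last_copy + 1))
        right_members = list(range(right.first_copy, right.last_copy + 1))
        sim_left = float(sim[np.ix_(run, left_members)].mean())
        sim_right = float(sim[np.ix_(run, right_members)].mean())
        cross = float(sim[np.ix_(left_members, right_members)].mean())
        is_barrier = sim_left < beta and sim_right < beta
        report.append({
            "run": (run[0], run[-1]),
            "similarity_left": sim_left,
            "similarity_right": sim_right,
            "flank_cross_similarity": cross,
            "barrier": is_barrier,
        })
        if is_barrier:
            barriers.append((run[0], run[-1]))
            unassigned -= set(run)
    # small domains not absorbed into a barrier stay domains
    in_barrier = set()
    for a, b in barriers:
        in_barrier.update(range(a, b + 1))
    for d in dmap.domains:
        if d not in major and d.first_copy not in in_barrier:
            new_domains.append(d)
    new_domains.sort(key=lambda d: d.first_copy)
    covered = set()
    for d in new_domains:
        covered.update(range(d.first_copy, d.last_copy + 1))
    for a, b in barriers:
        covered.update(range(a, b + 1))
    unassigned = set(range(dmap.n_copies)) - covered
    out = DomainMap(domains=new_domains, barriers=sorted(barriers),
                    unassigned=sorted(unassigned), n_copies=dmap.n_copies)
    return out, report


def detect_duplicate_pairs(alignment: ArrayAlignment,
                           partition: Optional[VariantPartition] = None,
                           min_identity: float = 0.995) -> list[DuplicatePair]:
    """Adjacent copy pairs at or above ``min_identity`` column identity.

    Such pairs are the expected immediate product of an unequal
    crossover duplicating one copy.  When a variant partition is given,
    each pair is annotated with the DVN groups private to exactly that
    pair — variants born on the copy before it was duplicated.
    """
    pairs = []
    for i in range(alignment.n_copies - 1):
        a, b = alignment.matrix[i], alignment.matrix[i + 1]
        ident = float(np.mean(a == b))
        if ident >= min_identity:
            n_private = 0
            if partition is not None:
                pair_ids = {alignment.copy_ids[i], alignment.copy_ids[i + 1]}
                n_private = sum(1 for g in partition.dvns
                                if set(g.carriers) == pair_ids)
            pairs.append(DuplicatePair(first_copy=i, second_copy=i + 1,
                                       identity=ident, n_private_dvns=n_private))
    return pairs


def detect_conversion_tracts(hm: HaplotypeMatrix, dmap: DomainMap,
                             k_min: int = 3) -> list[ConversionTract]:
    """Runs of foreign-domain DVNs on a copy, attributed to a donor domain.

    For a copy assigned to domain D, walk the DVN positions defining
    some other domain D' in consensus-column order; a position qualifies
    when the copy carries D''s state there (and not D's own defining
    state, where both domains define the same column).  Maximal runs of
    at least ``k_min`` consecutive qualifying positions are reported as
    conversion tracts with donor D'.
    """
    if k_min < 1:
        raise ParameterError("k_min must be >= 1")
    col_of = [g.column for g in hm.dvns]
    tracts: list[ConversionTract] = []
    for d_idx, dom in enumerate(dmap.domains):
        own = dom.defining_dvns
        own_cols = {col_of[g] for g in own}
        for donor_idx, donor in enumerate(dmap.domains):
            if donor_idx == d_idx:
                continue
            donor_groups = sorted(donor.defining_dvns - own, key=lambda g: col_of[g])
            if not donor_groups:
                continue
            for ci in range(dom.first_copy, dom.last_copy + 1):
                row = hm.matrix[ci]
                run: list[int] = []
                for g in donor_groups + [None]:  # sentinel flushes the last run
                    ok = False
                    if g is not None and row[g]:
                        if col_of[g] in own_cols:
                            same_col_own = [h for h in own if col_of[h] == col_of[g]]
                            ok = not any(row[h] for h in same_col_own)
                        else:
                            ok = True
                    if ok:
                        run.append(g)
                    else:
                        if len(run) >= k_min:
                            tracts.append(ConversionTract(
                                copy_id=hm.copy_ids[ci],
                                column_start=col_of[run[0]],
                                column_end=col_of[run[-1]] + 1,
                                donor_domain=donor_idx,
                                n_dvns=len(run)))
                        run = []
    tracts.sort(key=lambda t: (t.copy_id, t.column_start))
    return tracts


# ---------------------------------------------------------------------------
# set comparison (homologues; CENP-A vs bulk)


def intermingling_index(matrix_a: np.ndarray, matrix_b: np.ndarray,
                        n_perm: int = 999, seed: int = 0
                        ) -> tuple[float, float, float]:
    """Nearest-neighbour intermingling of two repeat sets in DVN space.

    The raw statistic is the fraction of repeats whose nearest non-self
    neighbour (haplotype Hamming distance) belongs to the other set,
    with co-minimal neighbours contributing fractionally.  It is
    normalised by its expectation under random labels — for a member of
    A that is ``|B| / (|A|+|B|-1)`` — so 1.0 means the two sets are as
    intermingled as a randomly labelled pool, and 0 means complete
    separation.  The p-value is one-sided (more intermingled than
    random) from ``n_perm`` label permutations.
    """
    a = np.asarray(matrix_a, dtype=np.int8)
    b = np.asarray(matrix_b, dtype=np.int8)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise EmptyInputError("intermingling undefined for an empty set")
    pool = np.vstack([a, b])
    labels = np.concatenate([np.zeros(a.shape[0], dtype=int),
                             np.ones(b.shape[0], dtype=int)])
    n = pool.shape[0]
    diff = (pool[:, None, :] != pool[None, :, :]).sum(axis=2)
    np.fill_diagonal(diff, diff.max() + 1)
    dmin = diff.min(axis=1)
    comin = diff == dmin[:, None]  # (n, n) co-minimal neighbour mask

    def raw_stat(lab: np.ndarray) -> float:
        other = lab[None, :] != lab[:, None]
        frac = (comin & other).sum(axis=1) / comin.sum(axis=1)
        return float(frac.mean())

    raw = raw_stat(labels)
    n_a, n_b = a.shape[0], b.shape[0]
    expect = (n_a * (n_b / (n - 1)) + n_b * (n_a / (n - 1))) / n
    index = raw / expect
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if raw_stat(perm) >= raw:
            hits += 1
    pvalue = (1 + hits) / (n_perm + 1)
    return index, raw, pvalue


def _linkage_newick(matrix: np.ndarray, ids: list[str]) -> str:
    """Average-linkage co-clustering tree on haplotype Hamming distance."""
    from skbio.tree import TreeNode

    diff = (matrix[:, None, :] != matrix[None, :, :]).sum(axis=2).astype(float)
    linkage = average(squareform(diff, checks=False))
    tree = TreeNode.from_linkage_matrix(linkage, ids)
    return str(tree).strip()


def compare_sets(copies_a, copies_b, n_perm: int = 999, seed: int = 0,
                 min_share: int = 2) -> SetComparison:
    """Compare two repeat sets in one joint consensus frame.

    Both sets are pooled, aligned to a joint consensus, and their DVNs
    recomputed on the pooled alignment; a DVN is *shared* when its
    carriers span both sets and *private* otherwise.  The haplotypes are
    co-clustered (average linkage on Hamming distance, emitted as
    newick) and the intermingling index quantifies how mixed the two
    sets are in DVN space.
    """
    from .variants import anchor_align, build_consensus, call_variants, classify_dvns

    ids_a, seqs_a = _label_set(copies_a, "A")
    ids_b, seqs_b = _label_set(copies_b, "B")
    if not ids_a or not ids_b:
        raise EmptyInputError("both sets must be non-empty")
    from .model import SequenceRecord

    pool = [SequenceRecord(id=i, sequence=s, source="setA") for i, s in zip(ids_a, seqs_a)]
    pool += [SequenceRecord(id=i, sequence=s, source="setB") for i, s in zip(ids_b, seqs_b)]
    cons = build_consensus(pool)
    aln = anchor_align(pool, consensus=cons)
    partition = classify_dvns(call_variants(aln), min_share=min_share)

    set_a = set(ids_a)
    shared = private_a = private_b = 0
    for g in partition.dvns:
        in_a = any(c in set_a for c in g.carriers)
        in_b = any(c not in set_a for c in g.carriers)
        if in_a and in_b:
            shared += 1
        elif in_a:
            private_a += 1
        else:
            private_b += 1

    hm = haplotype_matrix(partition, aln.copy_ids, ordered=False)
    mat_a = hm.matrix[: len(ids_a)]
    mat_b = hm.matrix[len(ids_a):]
    if hm.n_groups == 0:
        index, raw, pvalue = 1.0, float("nan"), 1.0
        newick = ""
    else:
        index, raw, pvalue = intermingling_index(mat_a, mat_b, n_perm=n_perm, seed=seed)
        newick = _linkage_newick(hm.matrix, aln.copy_ids)
    return SetComparison(shared_dvns=shared, private_a=private_a,
                         private_b=private_b, newick=newick,
                         intermingling_index=index, intermingling_raw=raw,
                         intermingling_pvalue=pvalue,
                         n_a=len(ids_a), n_b=len(ids_b))


def _label_set(copies, tag: str) -> tuple[list[str], list[str]]:
    from .variants import _as_strings

    ids, seqs = _as_strings(copies)
    return [f"{tag}:{i}" for i in ids], seqs
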