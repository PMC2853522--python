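"""Seeded end-to-end evaluations of every pipeline stage against ground truth.

Each function generates its own synthetic inputs (planted structures or
forward simulations), runs the relevant pipeline stages, and scores the
result against the generator's truth.  They are consumed by the
acceptance test-suite and by ``scripts/acceptance.py``; replicate counts
are part of each evaluation's definition.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import replace

import numpy as np
from scipy.stats import spearmanr

from . import sim
from .model import ArrayAlignment, SequenceRecord, STATE_ORDER
from .structure import (
    detect_barriers,
    detect_conversion_tracts,
    detect_duplicate_pairs,
    haplotype_matrix,
    intermingling_index,
    segment_domains,
)
from .variants import anchor_align, call_variants, classify_dvns, sporadic_rate
from .decompose import (
    detect_monomers,
    digest_insilico,
    extract_core,
    infer_hor_period,
    phase_hors,
)


def _sub_seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# archetypal-array end-to-end analysis


def archetype_analysis(seed: int = 0) -> dict:
    """Full pipeline on the simulator's D1Z5-like archetype.

    Returns both the measured quantities and the planted truth so the
    caller can judge agreement (unit count, period, unit length, DVN
    positions, domain boundaries, barrier, duplicate pair, modal
    restriction fragment).
    """
    t = sim.archetype_array(seed=seed)
    arr = SequenceRecord("array", t.sequence, source="archetype simulation")
    monomers = detect_monomers(arr)
    k, _profile = infer_hor_period(monomers, arr)
    phasing = phase_hors(monomers, arr, k, anchor=("restriction_site", t.site))
    core = extract_core(phasing)
    fragments = digest_insilico(arr, t.site)
    modal_fragment = Counter(fragments).most_common(1)[0][0]
    copies = [SequenceRecord(f"copy_{i + 1:03d}", t.sequence[u.start:u.end])
              for i, u in enumerate(core)]
    aln = anchor_align(copies)
    partition = classify_dvns(call_variants(aln))
    rate, _per_copy = sporadic_rate(partition, aln)
    hm = haplotype_matrix(partition, aln.copy_ids)
    dmap = segment_domains(hm)
    dmap, _report = detect_barriers(dmap, hm)
    pairs = detect_duplicate_pairs(aln, partition)
    tracts = detect_conversion_tracts(hm, dmap)
    return {
        "k": k,
        "n_core_units": len(core),
        "unit_length": core[0].length,
        "hor_length": aln.n_columns,
        "modal_fragment": modal_fragment,
        "dvn_columns": partition.dvn_columns,
        "sporadic_rate_percent": rate,
        "domains": [(d.first_copy, d.last_copy) for d in dmap.domains],
        "barriers": list(dmap.barriers),
        "duplicate_pairs": [(p.first_copy, p.second_copy) for p in pairs],
        "n_tracts": len(tracts),
        "truth": {
            "k": t.k,
            "n_core_units": t.n_core_units,
            "unit_length": t.unit_len,
            "dvn_columns": t.planted_dvn_columns,
            "domains": t.domains,
            "barrier": t.barrier,
            "duplicate_pair": t.duplicate_pair,
            "sporadic_rate_percent": 100.0 * t.sporadic_rate,
        },
    }


# ---------------------------------------------------------------------------
# DVN caller vs brute-force oracle


def brute_force_partition(rows: list[str], min_share: int = 2):
    """Independent enumeration oracle for variant calling + DVN classification.

    Recomputes the majority consensus by direct counting and walks every
    (copy, column) cell; returns hashable (dvn set, sporadic set).
    """
    n_cols = len(rows[0])
    consensus = []
    for j in range(n_cols):
        counts = Counter(r[j] for r in rows)
        top = max(counts.values())
        consensus.append(min((s for s, c in counts.items() if c == top),
                             key=STATE_ORDER.index))
    cells = {}
    for i, r in enumerate(rows):
        for j in range(n_cols):
            if r[j] != consensus[j]:
                cells.setdefault((j, r[j]), set()).add(i)
    dvns = frozenset((j, s, frozenset(c)) for (j, s), c in cells.items()
                     if len(c) >= min_share)
    sporadic = frozenset((i, j, s) for (j, s), c in cells.items()
                         if len(c) < min_share for i in c)
    return dvns, sporadic


def dvn_oracle_agreement(n_alignments: int = 200, seed: int = 0) -> float:
    """Fraction of random alignments where the pipeline's variant calling
    and DVN classification match the brute-force oracle exactly."""
    rng = np.random.default_rng(_sub_seed(seed, 1))
    agree = 0
    for _ in range(n_alignments):
        n = int(rng.integers(2, 9))
        width = int(rng.integers(5, 61))
        base = rng.integers(0, 4, size=width)
        mat = np.repeat(base[None, :], n, axis=0)
        n_noise = int(rng.integers(0, n * width // 3 + 1))
        ii = rng.integers(0, n, size=n_noise)
        jj = rng.integers(0, width, size=n_noise)
        mat[ii, jj] = rng.integers(0, 5, size=n_noise)  # 4 encodes '-'
        chars = np.array(list("ACGT-"))
        rows = ["".join(chars[r]) for r in mat]
        # pipeline path
        from .io import _majority_state

        matrix = np.array([list(r) for r in rows], dtype="<U1")
        consensus = "".join(_majority_state(matrix[:, j]) for j in range(width))
        aln = ArrayAlignment(copy_ids=[str(i) for i in range(n)], matrix=matrix,
                             consensus=consensus)
        part = classify_dvns(call_variants(aln))
        got_dvns = frozenset((g.column, g.alt_state,
                              frozenset(int(c) for c in g.carriers))
                             for g in part.dvns)
        got_spor = frozenset((int(v.copy_id), v.column, v.alt_state)
                             for v in part.sporadic)
        agree += (got_dvns, got_spor) == brute_force_partition(rows)
    return agree / n_alignments


# ---------------------------------------------------------------------------
# mutation-rate recovery


def mutation_rate_recovery(divergence: float, n_reps: int = 50, seed: int = 0,
                           n_copies: int = 30, unit_len: int = 652) -> dict:
    """Mutation-only simulations at a planted per-base divergence.

    Each replicate evolves identical copies for one generation at
    ``mu = divergence`` and measures the sporadic rate through the full
    consensus/alignment/classification path.
    """
    rates = []
    for r in range(n_reps):
        params = sim.SimParams(n0=n_copies, unit_len=unit_len, mu=divergence,
                               conv_rate=0.0, xo_rate=0.0, generations=1,
                               seed=_sub_seed(seed, 100 + r))
        _initial, final, _log = sim.simulate(params)
        copies = [SequenceRecord(f"c{i:03d}", s)
                  for i, s in enumerate(final.to_strings())]
        aln = anchor_align(copies)
        part = classify_dvns(call_variants(aln))
        rate, _ = sporadic_rate(part, aln)
        rates.append(rate)
    mean_rate = float(np.mean(rates))
    expected = 100.0 * divergence
    return {
        "planted_percent": expected,
        "recovered_percent": mean_rate,
        "relative_error": abs(mean_rate - expected) / expected,
    }


# ---------------------------------------------------------------------------
# planted-domain boundary recovery


def domain_boundary_recovery(n_reps: int = 100, seed: int = 0,
                             n_a: int = 20, n_b: int = 20) -> float:
    """Fraction of two-domain replicates whose boundary is recovered exactly."""
    exact = 0
    for r in range(n_reps):
        records, truth = sim.planted_domain_array(
            seed=_sub_seed(seed, 200 + r), n_a=n_a, n_b=n_b)
        aln = anchor_align(records)
        part = classify_dvns(call_variants(aln))
        hm = haplotype_matrix(part, aln.copy_ids)
        dmap = segment_domains(hm)
        doms = sorted((d.first_copy, d.last_copy) for d in dmap.domains)
        exact += doms == [(0, truth.boundary - 1),
                          (truth.boundary, n_a + n_b - 1)]
    return exact / n_reps


# ---------------------------------------------------------------------------
# conversion-tract detection


def conversion_tract_metrics(n_reps: int = 100, seed: int = 0,
                             tract_dvns: int = 5) -> dict:
    """Sensitivity and false-discovery rate of tract detection at defaults."""
    planted_total = detected = reported_total = false = 0
    tract_copies = (5, 12)
    for r in range(n_reps):
        records, truth = sim.planted_domain_array(
            seed=_sub_seed(seed, 300 + r), penetrance=(0.6, 0.9),
            tract_dvns=tract_dvns, tract_copies=tract_copies)
        aln = anchor_align(records)
        part = classify_dvns(call_variants(aln))
        hm = haplotype_matrix(part, aln.copy_ids)
        dmap = segment_domains(hm)
        tracts = detect_conversion_tracts(hm, dmap)
        planted_ids = {records[ci].id for ci in tract_copies}
        planted_total += len(tract_copies)
        hit_ids = set()
        for t in tracts:
            reported_total += 1
            if t.copy_id in planted_ids:
                hit_ids.add(t.copy_id)
            else:
                false += 1
        detected += len(hit_ids)
    return {
        "sensitivity": detected / planted_total,
        "false_discovery_rate": false / reported_total if reported_total else 0.0,
        "n_reported": reported_total,
    }


# ---------------------------------------------------------------------------
# intermingling calibration


def intermingling_random_labels(seed: int = 0, n_draws: int = 30) -> float:
    """Mean normalized intermingling of randomly bipartitioned pooled repeats.

    Under exchangeable labels the index calibrates to ~1.0; averaging
    over label draws removes the single-draw sampling noise (sd ~0.16
    at 40 copies) so the calibration itself is what is measured.
    """
    records, _truth = sim.planted_domain_array(seed=_sub_seed(seed, 400),
                                               penetrance=(0.5, 0.9))
    aln = anchor_align(records)
    part = classify_dvns(call_variants(aln))
    hm = haplotype_matrix(part, aln.copy_ids)
    rng = np.random.default_rng(_sub_seed(seed, 401))
    half = hm.n_copies // 2
    indices = []
    for _ in range(n_draws):
        perm = rng.permutation(hm.n_copies)
        index, _raw, _p = intermingling_index(
            hm.matrix[perm[:half]], hm.matrix[perm[half:]],
            n_perm=0, seed=0)
        indices.append(index)
    return float(np.mean(indices))


def intermingling_separated(seed: int = 0) -> float:
    """Raw nearest-neighbour statistic for fully separated haplotype clusters
    (must be exactly 0)."""
    rng = np.random.default_rng(_sub_seed(seed, 410))
    n, g = 12, 24
    mat_a = np.zeros((n, g), dtype=np.int8)
    mat_b = np.zeros((n, g), dtype=np.int8)
    mat_a[:, : g // 2] = rng.integers(0, 2, size=(n, g // 2))
    mat_a[:, 0] = 1  # anchor so clusters cannot overlap at the all-zero point
    mat_b[:, g // 2 :] = rng.integers(0, 2, size=(n, g // 2))
    mat_b[:, g // 2] = 1
    _index, raw, _p = intermingling_index(mat_a, mat_b, n_perm=99, seed=0)
    return float(raw)


# ---------------------------------------------------------------------------
# simulator self-checks


def replay_exactness(n_cases: int = 20, seed: int = 0) -> float:
    """Fraction of random parameterisations whose event-log replay
    reproduces the final array bit-exactly."""
    rng = np.random.default_rng(_sub_seed(seed, 500))
    exact = 0
    for r in range(n_cases):
        params = sim.SimParams(
            n0=int(rng.integers(8, 25)),
            unit_len=int(rng.integers(150, 500)),
            mu=float(rng.uniform(1e-5, 5e-4)),
            conv_rate=float(rng.uniform(0, 0.5)),
            conv_tract_mean=float(rng.uniform(20, 120)),
            xo_rate=float(rng.uniform(0, 0.5)),
            xo_identity_min=float(rng.uniform(0.90, 0.99)),
            xo_offset_max=int(rng.integers(1, 5)),
            generations=int(rng.integers(10, 80)),
            seed=_sub_seed(seed, 501 + r),
        )
        _initial, final, log = sim.simulate(params)
        replayed = sim.replay(log)
        exact += (len(replayed) == final.n_copies and
                  all(np.array_equal(a, b)
                      for a, b in zip(replayed, final.copies)))
    return exact / n_cases


def _mean_pairwise_identity(array: sim.SimArray) -> float:
    mat = np.stack(array.copies)
    n = mat.shape[0]
    total = pairs = 0.0
    for i in range(n - 1):
        total += float((mat[i + 1 :] == mat[i]).mean(axis=1).sum())
        pairs += n - i - 1
    return total / pairs


def homogenisation_effect(n_reps: int = 20, seed: int = 0) -> dict:
    """Within-array identity with unequal crossover on vs off.

    Crossovers duplicate near-identical neighbours, purging diversity;
    at equal elapsed generations the crossover-on arrays must stay more
    homogeneous than mutation-only arrays.
    """
    on, off = [], []
    for r in range(n_reps):
        base = dict(n0=20, unit_len=300, mu=1e-4, conv_rate=0.0,
                    conv_tract_mean=50.0, xo_identity_min=0.95,
                    xo_offset_max=3, generations=120,
                    seed=_sub_seed(seed, 600 + r))
        for xo, sink in ((1.0, on), (0.0, off)):
            params = sim.SimParams(xo_rate=xo, **base)
            _i, final, _log = sim.simulate(params)
            sink.append(_mean_pairwise_identity(final))
    return {"identity_crossover_on": float(np.mean(on)),
            "identity_crossover_off": float(np.mean(off)),
            "n_on_higher": int(np.sum(np.array(on) > np.array(off)))}


def shared_dvn_trend(n_reps: int = 20, n_points: int = 10, seed: int = 0
                     ) -> dict:
    """Shared-DVN fraction between split lineages versus separation time.

    Homologues separated longer share fewer DVNs; the trend over
    ``n_points`` separation times must be negative (Spearman).  The
    separation range stays below the regime where coincidental
    same-column variants in both lineages start inflating the shared
    count.
    """
    from .structure import compare_sets

    g_values = np.linspace(10, 150, n_points).astype(int)
    mean_shared = []
    for g in g_values:
        fracs = []
        for r in range(n_reps):
            params = sim.SimParams(n0=15, unit_len=300, mu=2e-4, conv_rate=0.1,
                                   conv_tract_mean=40.0, xo_rate=0.4,
                                   xo_identity_min=0.90, xo_offset_max=3,
                                   generations=60,
                                   seed=_sub_seed(seed, 700 + r))
            _i, ancestor_array, _log = sim.simulate(params)
            a, b = sim.split_lineages(ancestor_array, params, int(g))
            sc = compare_sets(
                [SequenceRecord(f"a{i}", s) for i, s in enumerate(a.to_strings())],
                [SequenceRecord(f"b{i}", s) for i, s in enumerate(b.to_strings())],
                n_perm=19, seed=_sub_seed(seed, 710 + r))
            if sc.total_dvns:
                fracs.append(sc.shared_dvns / sc.total_dvns)
        mean_shared.append(float(np.mean(fracs)))
    rho, pvalue = spearmanr(g_values, mean_shared)
    return {"g_values": g_values.tolist(), "mean_shared_fraction": mean_shared,
            "spearman_rho": float(rho), "pvalue": float(pvalue)}
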