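"""Built-in fallback aligner.

Produces BLAST-style 12-column alignment hits without external binaries:
candidate pairs are found by shared exact k-mer seeds, then scored with an
exact local affine-gap alignment (Biopython's C implementation).  Bit
scores follow the Karlin-Altschul form bit = (lambda*S - ln K) / ln 2 with
standard ungapped constants, and E = m*n*2^(-bit) over the full sequence
lengths.  This is a simplified E-value dialect: adequate for separating
true homologs from chance matches at desk scale, not a BLAST replacement.
External aligner output in the same tabular format is accepted everywhere
this module's output is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .sequence_io import AlignmentHit, SeqRecord

# Karlin-Altschul constants: BLOSUM62 (gapped 11/1 regime) and +2/-3 nucleotide
_PROT_LAMBDA, _PROT_K = 0.267, 0.041
_NT_LAMBDA, _NT_K = 0.625, 0.41


def _hit_from_alignment(
    aln, query: SeqRecord, subject: SeqRecord, lam: float, k_const: float,
    qoff: int = 0, soff: int = 0,
) -> AlignmentHit:
    counts = aln.counts()
    identities, mismatches, gaps = counts.identities, counts.mismatches, counts.gaps
    length = identities + mismatches + gaps
    # count gap openings from the aligned block structure
    qa, sa = aln.aligned
    gapopen = max(len(qa) - 1, 0) + max(len(sa) - 1, 0)
    bit = (lam * aln.score - math.log(k_const)) / math.log(2)
    evalue = len(query.sequence) * len(subject.sequence) * 2.0 ** (-bit)
    return AlignmentHit(
        query_id=query.id,
        subject_id=subject.id,
        pct_identity=100.0 * identities / max(length, 1),
        align_len=int(length),
        mismatch=int(mismatches),
        gapopen=int(gapopen),
        qstart=int(qa[0][0]) + qoff + 1,
        qend=int(qa[-1][1]) + qoff,
        sstart=int(sa[0][0]) + soff + 1,
        send=int(sa[-1][1]) + soff,
        evalue=float(evalue),
        bitscore=float(bit),
    )


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def align_proteins(
    records: list[SeqRecord],
    evalue_max: float = 10.0,
    seed_k: int = 5,
    min_shared_seeds: int = 3,
) -> list[AlignmentHit]:
    """All-vs-all local protein alignment over seed-sharing pairs.

    Only unordered pairs sharing at least ``min_shared_seeds`` exact
    ``seed_k``-mers are aligned (BLOSUM62, gap open 11 / extend 1); one hit
    per pair is emitted, query = the earlier record.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0

    kmer_index: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        for kmer in _kmer_set(rec.sequence, seed_k):
            kmer_index.setdefault(kmer, []).append(i)
    pair_counts: dict[tuple[int, int], int] = {}
    for members in kmer_index.values():
        if len(members) < 2 or len(members) > 200:
            continue
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                key = (members[a], members[b])
                pair_counts[key] = pair_counts.get(key, 0) + 1

    hits: list[AlignmentHit] = []
    for (i, j), count in sorted(pair_counts.items()):
        if count < min_shared_seeds:
            continue
        q, s = records[i], records[j]
        alns = aligner.align(q.sequence, s.sequence)
        if len(alns) == 0 or alns[0].score <= 0:
            continue
        hit = _hit_from_alignment(alns[0], q, s, _PROT_LAMBDA, _PROT_K)
        if hit.evalue <= evalue_max:
            hits.append(hit)
    return hits


def _encode(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """2-bit encode; second array flags valid (ACGT) positions."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = np.zeros(arr.shape, dtype=np.int64)
    valid = np.zeros(arr.shape, dtype=bool)
    for code, ch in enumerate(b"ACGT"):
        m = arr == ch
        codes[m] = code
        valid |= m
    return codes, valid


def _rolling_kmers(codes: np.ndarray, valid: np.ndarray, k: int) -> np.ndarray:
    """Integer id of each k-mer window; -1 where the window contains non-ACGT."""
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    vals = win @ powers
    ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    return np.where(ok, vals, -1)


def align_nucleotide(
    queries: list[SeqRecord],
    subjects: list[SeqRecord],
    evalue_max: float = 10.0,
    seed_k: int = 15,
    margin: int = 100,
    diag_band: int = 60,
    max_regions: int = 20,
) -> list[AlignmentHit]:
    """Seed-and-extend local nucleotide alignment of queries vs subjects.

    Exact ``seed_k``-mer matches are grouped by diagonal into candidate
    regions; each region is aligned exactly (match +2 / mismatch -3, gap
    open 5 / extend 2) on windowed substrings, and the best-scoring region
    per query-subject pair is reported as one hit.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0

    # index subjects: sorted k-mer arrays for binary search
    subj_index = []
    for s in subjects:
        codes, valid = _encode(s.sequence)
        kmers = _rolling_kmers(codes, valid, seed_k)
        order = np.argsort(kmers, kind="stable")
        subj_index.append((kmers[order], order))

    hits: list[AlignmentHit] = []
    for q in queries:
        codes, valid = _encode(q.sequence)
        qkmers = _rolling_kmers(codes, valid, seed_k)
        qpos_all = np.flatnonzero(qkmers >= 0)
        if qpos_all.size == 0:
            continue
        qvals = qkmers[qpos_all]
        for sidx, (skmers_sorted, sorder) in enumerate(subj_index):
            s = subjects[sidx]
            lo = np.searchsorted(skmers_sorted, qvals, side="left")
            hi = np.searchsorted(skmers_sorted, qvals, side="right")
            match_mask = hi > lo
            if not match_mask.any():
                continue
            seed_q: list[int] = []
            seed_s: list[int] = []
            for qi, l, h in zip(qpos_all[match_mask], lo[match_mask], hi[match_mask]):
                for sp in sorder[l:h]:
                    seed_q.append(int(qi))
                    seed_s.append(int(sp))
            seed_q_arr = np.array(seed_q)
            seed_s_arr = np.array(seed_s)
            diag = seed_s_arr - seed_q_arr
            order = np.lexsort((seed_q_arr, diag))
            # group seeds into regions: same diagonal band, nearby on query
            regions: list[tuple[int, int, int, int, int]] = []  # q0,q1,s0,s1,nseeds
            cur = None
            for idx in order:
                dq, qq, ss = int(diag[idx]), int(seed_q_arr[idx]), int(seed_s_arr[idx])
                if (
                    cur is not None
                    and abs(dq - cur[5]) <= diag_band
                    and qq - cur[1] <= 2 * margin
                ):
                    cur = (cur[0], max(cur[1], qq), cur[2], max(cur[3], ss), cur[4] + 1, dq)
                else:
                    if cur is not None:
                        regions.append(cur[:5])
                    cur = (qq, qq, ss, ss, 1, dq)
            if cur is not None:
                regions.append(cur[:5])
            regions.sort(key=lambda r: -r[4])
            best: AlignmentHit | None = None
            for q0, q1, s0, s1, _ in regions[:max_regions]:
                qa, qb = max(0, q0 - margin), min(len(q.sequence), q1 + seed_k + margin)
                sa, sb = max(0, s0 - margin), min(len(s.sequence), s1 + seed_k + margin)
                alns = aligner.align(q.sequence[qa:qb], s.sequence[sa:sb])
                if len(alns) == 0 or alns[0].score <= 0:
                    continue
                hit = _hit_from_alignment(alns[0], q, s, _NT_LAMBDA, _NT_K, qoff=qa, soff=sa)
                if best is None or hit.bitscore > best.bitscore:
                    best = hit
            if best is not None and best.evalue <= evalue_max:
                hits.append(best)
    return hits
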