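"""Per-molecule CpG methylation calling from amplicon bisulfite reads.

Reads are demultiplexed to targets by bisulfite-degenerate forward-primer
identity (threshold 0.8), length-filtered against the amplicon (relative
deviation at most 0.2), aligned to the in-silico converted reference with a
bisulfite-aware semi-global alignment, and each CpG position is called:

* ``1`` — cytosine retained (methylated),
* ``0`` — cytosine converted to thymine (unmethylated),
* ``2`` — any other base or a gap (mismatch).

Bisulfite-degenerate matching means a reference C outside CpG context
matches both T (converted) and C (conversion failure), and a reference C at
a declared CpG offset matches both C and T, the methylation state being read
out at the calling step rather than penalised during alignment.

The module offers a per-read API (:func:`assign_read`, :func:`bisulfite_align`,
:func:`call_cpg_states`) and a vectorised batch API (:func:`call_reads`) that
exploits the fact that indel-free amplicon reads all share the amplicon
length, falling back to dynamic programming only for length-discordant reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from bcfdna.targets import AmpliconTarget, TargetPanel
from bcfdna.synthetic_data import ReadBatch

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class CallerConfig:
    """Demultiplexing, filtering and alignment parameters."""

    primer_similarity_min: float = 0.8
    length_tolerance: float = 0.2
    match_score: int = 1
    mismatch_score: int = -1
    gap_score: int = -2
    #: a read is discarded as unalignable below this fraction of the maximum
    #: attainable alignment score
    score_floor_fraction: float = 0.6
    try_reverse_complement: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.primer_similarity_min <= 1.0:
            raise ValueError("primer_similarity_min must be in [0, 1]")
        if not 0.0 <= self.length_tolerance < 1.0:
            raise ValueError("length_tolerance must be in [0, 1)")


def primer_identity(read: str, primer: str) -> float:
    """Bisulfite-degenerate identity of a read prefix against a primer.

    Computed over the first ``len(primer)`` bases of the read: a position
    matches when the bases are equal or when the primer has C and the read T.
    """
    if not primer:
        return 0.0
    prefix = read[: len(primer)]
    matches = sum(
        1
        for p, r in zip(primer, prefix)
        if p == r or (p == "C" and r == "T")
    )
    return matches / len(primer)


def assign_read(
    read: str, targets: TargetPanel, cfg: CallerConfig = CallerConfig()
) -> tuple[str | None, bool]:
    """Assign a read to the target with the best forward-primer identity.

    Returns ``(target_name, was_reverse_complemented)``; ``(None, False)``
    if no target reaches ``primer_similarity_min`` or the best identity is
    tied between targets.
    """
    if len(targets) == 0:
        raise ValueError("no targets defined")
    if not read:
        return None, False
    name = _assign_forward(read, targets, cfg)
    if name is not None:
        return name, False
    if cfg.try_reverse_complement:
        rc = reverse_complement(read)
        name = _assign_forward(rc, targets, cfg)
        if name is not None:
            return name, True
    return None, False


def _assign_forward(read: str, targets: TargetPanel, cfg: CallerConfig) -> str | None:
    sims = [(primer_identity(read, t.fwd_primer), t.name) for t in targets]
    best = max(s for s, _ in sims)
    if best < cfg.primer_similarity_min:
        return None
    winners = [n for s, n in sims if s == best]
    if len(winners) != 1:
        return None
    return winners[0]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def length_filter(read: str, target: AmpliconTarget, cfg: CallerConfig = CallerConfig()) -> bool:
    """Relative length deviation from the amplicon, boundary inclusive."""
    dev = abs(len(read) - target.length) / target.length
    return dev <= cfg.length_tolerance


# ---------------------------------------------------------------------------
# alignment


def _pair_score_table(target: AmpliconTarget, cfg: CallerConfig) -> np.ndarray:
    """(ref_position, read_base_index) -> score, bases indexed in 'ACGT-'."""
    ref = target.reference_sequence
    cpg = set(target.cpg_offsets)
    table = np.full((len(ref), 5), cfg.mismatch_score, dtype=np.int32)
    base_to_idx = {b: i for i, b in enumerate("ACGT")}
    for i, rb in enumerate(ref):
        if rb == "C":
            # C matches C; T matches both in and out of CpG context
            table[i, base_to_idx["C"]] = cfg.match_score
            table[i, base_to_idx["T"]] = cfg.match_score
        elif rb in base_to_idx:
            table[i, base_to_idx[rb]] = cfg.match_score
    return table


def bisulfite_align(
    read: str, target: AmpliconTarget, cfg: CallerConfig = CallerConfig()
) -> tuple[str | None, int, int]:
    """Semi-global bisulfite-aware alignment of a read to the reference.

    Returns ``(ref_aligned_read, score, max_score)`` where
    ``ref_aligned_read`` has one symbol per reference position (the read base
    consumed there, or ``-`` for a gap / unaligned end) or ``None`` when the
    score falls below the configured floor. End gaps are free on both
    sequences; traceback is deterministic, preferring diagonal, then up
    (gap in the read), then left (insertion in the read).
    """
    ref = target.reference_sequence
    max_score = cfg.match_score * min(len(read), len(ref))
    floor = cfg.score_floor_fraction * max_score
    if len(read) == len(ref):
        # identity fast path: with at most a couple of mismatching columns, an
        # alignment with k >= 1 indel pairs scores at most
        # max - k*(match - 2*gap), so the gap-free alignment is optimal
        score = _columnwise_score(read, target, cfg)
        if score > max_score - _identity_margin(cfg):
            return read, score, max_score
    aligned, score = _needleman_wunsch(read, target, cfg)
    if score < floor:
        return None, score, max_score
    return aligned, score, max_score


def _identity_margin(cfg: CallerConfig) -> int:
    return cfg.match_score - 2 * cfg.gap_score


def _columnwise_score(read: str, target: AmpliconTarget, cfg: CallerConfig) -> int:
    table = _pair_score_table(target, cfg)
    idx = np.frombuffer(read.encode(), dtype=np.uint8)
    col = np.full(idx.shape, 4, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        col[idx == b] = i
    rows = np.arange(len(read))
    vals = table[rows, np.minimum(col, 3)]
    vals = np.where(col == 4, cfg.mismatch_score, vals)
    return int(vals.sum())


def _needleman_wunsch(
    read: str, target: AmpliconTarget, cfg: CallerConfig
) -> tuple[str, int]:
    ref = target.reference_sequence
    n, m = len(ref), len(read)
    table = _pair_score_table(target, cfg)
    read_idx = np.array(
        [("ACGT".index(b) if b in "ACGT" else 4) for b in read], dtype=np.int64
    )
    pair = np.where(
        read_idx[None, :] < 4,
        table[:, np.minimum(read_idx, 3)],
        cfg.mismatch_score,
    )  # (n, m)

    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    move = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 diag, 2 up, 3 left
    gap = cfg.gap_score
    j_idx = np.arange(1, m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        diag = H[i - 1, :-1] + pair[i - 1]
        up = H[i - 1, 1:] + gap
        best_du = np.where(diag >= up, diag, up)
        mv_du = np.where(diag >= up, 1, 2).astype(np.int8)
        # resolve the left-gap dependency with a prefix-max scan: a left run
        # entered after cell k contributes best_du[k-1] + gap * (j - k)
        d = np.empty(m + 1, dtype=np.int64)
        d[0] = 0  # entering from the free row[0]
        d[1:] = best_du.astype(np.int64) - gap * j_idx
        left = gap * j_idx + np.maximum.accumulate(d)[:-1]
        row = np.empty(m + 1, dtype=np.int32)
        row[0] = 0  # free leading gap in the read
        take_left = left > best_du
        row[1:] = np.where(take_left, left, best_du)
        mv = np.empty(m + 1, dtype=np.int8)
        mv[0] = 2
        mv[1:] = np.where(take_left, np.int8(3), mv_du)
        H[i] = row
        move[i] = mv

    # free trailing gaps: best over last row and last column, preferring the
    # corner, then the last column bottom-up, then the last row right-to-left
    best_i, best_j = n, m
    best = H[n, m]
    for i in range(n - 1, 0, -1):
        if H[i, m] > best:
            best, best_i, best_j = H[i, m], i, m
    for j in range(m - 1, 0, -1):
        if H[n, j] > best:
            best, best_i, best_j = H[n, j], n, j

    aligned = ["-"] * n
    i, j = best_i, best_j
    while i > 0 and j > 0:
        mv = move[i, j]
        if mv == 1:
            aligned[i - 1] = read[j - 1]
            i -= 1
            j -= 1
        elif mv == 2:
            aligned[i - 1] = "-"
            i -= 1
        else:
            j -= 1
    return "".join(aligned), int(best)


def _nw_batch(
    sub: np.ndarray, target: AmpliconTarget, cfg: CallerConfig
) -> list[tuple[str | None, int]]:
    """Dynamic-programming alignment vectorised across equal-length reads.

    Same recurrence, tie rules and traceback as :func:`_needleman_wunsch`,
    applied to a (k, L) read byte matrix; returns ``(ref_aligned_read,
    score)`` per read with ``None`` for reads below the score floor.
    """
    ref = target.reference_sequence
    n = len(ref)
    k, m = sub.shape
    table = _pair_score_table(target, cfg)
    col = np.full(sub.shape, 4, dtype=np.int64)
    for bi, b in enumerate(b"ACGT"):
        col[sub == b] = bi
    gap = cfg.gap_score
    j_idx = np.arange(1, m + 1, dtype=np.int64)

    H = np.zeros((k, m + 1), dtype=np.int64)
    move = np.zeros((k, n + 1, m + 1), dtype=np.int8)
    lastcol = np.zeros((k, n + 1), dtype=np.int64)
    for i in range(1, n + 1):
        pair_i = np.where(col < 4, table[i - 1, np.minimum(col, 3)], cfg.mismatch_score)
        diag = H[:, :-1] + pair_i
        up = H[:, 1:] + gap
        ge = diag >= up
        best_du = np.where(ge, diag, up)
        mv_du = np.where(ge, 1, 2).astype(np.int8)
        d = np.empty((k, m + 1), dtype=np.int64)
        d[:, 0] = 0
        d[:, 1:] = best_du - gap * j_idx
        left = gap * j_idx + np.maximum.accumulate(d, axis=1)[:, :-1]
        take_left = left > best_du
        newH = np.empty_like(H)
        newH[:, 0] = 0
        newH[:, 1:] = np.where(take_left, left, best_du)
        mv = move[:, i, :]
        mv[:, 0] = 2
        mv[:, 1:] = np.where(take_left, np.int8(3), mv_du)
        H = newH
        lastcol[:, i] = H[:, m]

    max_score = cfg.match_score * min(n, m)
    floor = cfg.score_floor_fraction * max_score
    out: list[tuple[str | None, int]] = []
    reads = [bytes(row).decode("ascii") for row in sub]
    for r in range(k):
        # endpoint preference: corner, then last column bottom-up, then last row
        best_i, best_j = n, m
        best = int(lastcol[r, n])
        for i in range(n - 1, 0, -1):
            if lastcol[r, i] > best:
                best, best_i, best_j = int(lastcol[r, i]), i, m
        for j in range(m - 1, 0, -1):
            if H[r, j] > best:
                best, best_i, best_j = int(H[r, j]), n, j
        if best < floor:
            out.append((None, best))
            continue
        aligned = ["-"] * n
        i, j = best_i, best_j
        read = reads[r]
        mv_r = move[r]
        while i > 0 and j > 0:
            mv = mv_r[i, j]
            if mv == 1:
                aligned[i - 1] = read[j - 1]
                i -= 1
                j -= 1
            elif mv == 2:
                aligned[i - 1] = "-"
                i -= 1
            else:
                j -= 1
        out.append(("".join(aligned), best))
    return out


def call_cpg_states(ref_aligned_read: str, target: AmpliconTarget) -> str:
    """Call string over the target's CpG offsets from a ref-aligned read."""
    out = []
    for off in target.cpg_offsets:
        b = ref_aligned_read[off]
        out.append("1" if b == "C" else "0" if b == "T" else "2")
    return "".join(out)


def call_single_read(
    read: str, targets: TargetPanel, cfg: CallerConfig = CallerConfig()
) -> tuple[str | None, str | None, str]:
    """Full per-read pipeline: (target, call_string, status)."""
    name, rc = assign_read(read, targets, cfg)
    if name is None:
        return None, None, "unassigned"
    target = targets[name]
    seq = reverse_complement(read) if rc else read
    if not length_filter(seq, target, cfg):
        return name, None, "length_fail"
    aligned, _, _ = bisulfite_align(seq, target, cfg)
    if aligned is None:
        return name, None, "unalignable"
    return name, call_cpg_states(aligned, target), "called"


# ---------------------------------------------------------------------------
# batch API


@dataclass
class CallResult:
    """Per-read call strings plus per-target processing counts."""

    calls: pd.DataFrame      # read_id, sample_id, target, call_string
    summary: pd.DataFrame    # target, assigned, called, unassigned, length_fail, unalignable


def _batch_primer_identity(mat: np.ndarray, primer: str) -> np.ndarray:
    """Vectorised bisulfite-degenerate identity of read prefixes (n,)."""
    L = min(len(primer), mat.shape[1])
    if L == 0:
        return np.zeros(mat.shape[0])
    prefix = mat[:, :L]
    p = np.frombuffer(primer.encode(), dtype=np.uint8)[:L]
    eq = prefix == p
    degen = (p == ord("C")) & (prefix == ord("T"))
    return (eq | degen).sum(axis=1) / len(primer)


def call_reads(
    batch: ReadBatch,
    targets: TargetPanel,
    cfg: CallerConfig = CallerConfig(),
) -> CallResult:
    """Call every read of a batch, vectorising the indel-free common case.

    Reads whose length equals the assigned amplicon's length are demultiplexed,
    scored and called with matrix operations; length-discordant reads take the
    per-read dynamic-programming path.
    """
    seq_list: list[str] | None = None
    counts: dict[str, dict[str, int]] = {
        t.name: dict(assigned=0, called=0, unassigned=0, length_fail=0, unalignable=0)
        for t in targets
    }
    counts["__none__"] = dict(assigned=0, called=0, unassigned=0, length_fail=0, unalignable=0)
    rows: list[tuple[int, str, str, str, str]] = []

    if batch.matrix is not None:
        mat = batch.matrix
        n = mat.shape[0]
        sims = np.stack(
            [_batch_primer_identity(mat, t.fwd_primer) for t in targets], axis=1
        )  # (n, n_targets)
        best = sims.max(axis=1)
        argbest = sims.argmax(axis=1)
        tie = (sims == best[:, None]).sum(axis=1) > 1
        ok = (best >= cfg.primer_similarity_min) & ~tie
        ids = batch.read_ids() if n else []
        for ti, t in enumerate(targets):
            sel = np.flatnonzero(ok & (argbest == ti))
            if sel.size == 0:
                continue
            counts[t.name]["assigned"] += int(sel.size)
            if not length_filter("x" * mat.shape[1], t, cfg):
                counts[t.name]["length_fail"] += int(sel.size)
                continue
            if mat.shape[1] == t.length:
                sub = mat[sel]
                score_tab = _pair_score_table(t, cfg)
                col_scores = _matrix_scores(sub, score_tab, cfg)
                # fast path only where the gap-free alignment is provably optimal
                good = col_scores > cfg.match_score * t.length - _identity_margin(cfg)
                called_idx = sel[good]
                calls = _matrix_calls(mat[called_idx], t)
                counts[t.name]["called"] += len(called_idx)
                for k, ci in enumerate(called_idx):
                    rows.append((int(ci), ids[ci], batch.sample_id, t.name, calls[k]))
                dp_idx = sel[~good]
            else:
                dp_idx = sel
            # length-discordant or low-identity reads: batched DP alignment
            if len(dp_idx):
                for ci, (aligned, _) in zip(dp_idx, _nw_batch(mat[dp_idx], t, cfg)):
                    if aligned is None:
                        counts[t.name]["unalignable"] += 1
                    else:
                        counts[t.name]["called"] += 1
                        rows.append(
                            (int(ci), ids[ci], batch.sample_id, t.name, call_cpg_states(aligned, t))
                        )
        n_unassigned = int((~ok).sum())
        counts["__none__"]["unassigned"] += n_unassigned
        # reverse-complement retry for unassigned reads
        if cfg.try_reverse_complement and n_unassigned:
            for ci in np.flatnonzero(~ok):
                seq = bytes(mat[ci]).decode("ascii")
                name, call, status = call_single_read(seq, targets, cfg)
                if status == "called":
                    counts["__none__"]["unassigned"] -= 1
                    counts[name]["assigned"] += 1
                    counts[name]["called"] += 1
                    rows.append((int(ci), ids[ci], batch.sample_id, name, call))
    else:
        seq_list = batch.sequences
        ids = batch.read_ids()
        for i, (rid, seq) in enumerate(zip(ids, seq_list)):
            name, call, status = call_single_read(seq, targets, cfg)
            key = name if name is not None else "__none__"
            if status == "called":
                counts[key]["assigned"] += 1
                counts[key]["called"] += 1
                rows.append((i, rid, batch.sample_id, name, call))
            elif status == "unassigned":
                counts["__none__"]["unassigned"] += 1
            else:
                counts[key]["assigned"] += 1
                counts[key][status] += 1

    rows.sort(key=lambda r: r[0])
    calls_df = pd.DataFrame(
        [r[1:] for r in rows], columns=["read_id", "sample_id", "target", "call_string"]
    )
    summary = (
        pd.DataFrame(counts)
        .T.rename_axis("target")
        .reset_index()
    )
    return CallResult(calls=calls_df, summary=summary)


def _matrix_scores(sub: np.ndarray, score_tab: np.ndarray, cfg: CallerConfig) -> np.ndarray:
    """Identity-alignment scores for a (n, L) read matrix."""
    n, L = sub.shape
    col = np.full(sub.shape, 4, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        col[sub == b] = i
    rows = np.broadcast_to(np.arange(L), (n, L))
    vals = score_tab[rows, np.minimum(col, 3)]
    vals = np.where(col == 4, cfg.mismatch_score, vals)
    return vals.sum(axis=1)


def _matrix_calls(sub: np.ndarray, target: AmpliconTarget) -> list[str]:
    """Vectorised CpG calling for identity-aligned reads."""
    offs = np.asarray(target.cpg_offsets, dtype=int)
    bases = sub[:, offs]
    out = np.full(bases.shape, ord("2"), dtype=np.uint8)
    out[bases == ord("C")] = ord("1")
    out[bases == ord("T")] = ord("0")
    return [bytes(row).decode("ascii") for row in out]


def call_sample(
    batches: Mapping[str, ReadBatch],
    targets: TargetPanel,
    cfg: CallerConfig = CallerConfig(),
) -> CallResult:
    """Call a whole sample given per-target read batches; concatenates results."""
    parts = [call_reads(b, targets, cfg) for b in batches.values()]
    calls = pd.concat([p.calls for p in parts], ignore_index=True)
    summary = (
        pd.concat([p.summary for p in parts], ignore_index=True)
        .groupby("target", as_index=False)
        .sum(numeric_only=True)
    )
    return CallResult(calls=calls, summary=summary)
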