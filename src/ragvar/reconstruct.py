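"""On-the-fly reconstruction of fixed-length personalized haplotypes.

Given a reference window ``[start, end + max_extension)``, a position-sorted
non-overlapping variant list for one haplotype, and a target length, the
cursor algorithm splices alleles left to right:

* for each variant at ``p``: emit ``ref[cursor:p)``, emit the alt allele,
  advance the cursor to ``p + len(ref_allele)``;
* variants starting before the cursor were swallowed by an applied
  deletion and are skipped;
* a deletion spanning the window start consumes only its in-window REF
  portion and contributes no alt bases;
* the trailing reference is appended, the output truncated to the target
  length, and — only if the window itself runs out (deletions at a contig
  end) — padded with ``N``.

Track re-alignment is the same edit applied to per-base values: deleted
reference positions contribute nothing, each inserted base duplicates the
value at its variant's anchor position, and substitutions keep the original
value. Both paths are driven by a single *edit plan* (per output base, the
window offset it derives from), which makes the sequence/track consistency
guarantee structural rather than incidental.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import VariantRecord
from .errors import CorruptStoreError, InvalidInputError

__all__ = [
    "HaplotypeResult",
    "intervals_to_values",
    "reconstruct_haplotype",
    "realign_track",
    "project_coordinate",
    "orient",
    "reverse_complement",
]

_PAD = -1  # edit-plan sentinel: window exhausted, emit N / 0.0


@dataclass(frozen=True)
class HaplotypeResult:
    """A fixed-length personalized sequence plus its provenance map.

    ``sequence`` is a byte vector (dtype ``S1``, uppercase A/C/G/T/N) of
    exactly the target length. ``source_map[i]`` is the 0-based reference
    position output base ``i`` derives from; inserted bases carry their
    variant's anchor position, so the map is non-decreasing.
    """

    sequence: np.ndarray
    source_map: np.ndarray

    def __len__(self) -> int:
        return self.sequence.size


def _edit_plan(
    window_len: int,
    window_start: int,
    variants: Sequence[VariantRecord],
    target_length: int,
) -> tuple[np.ndarray, list[tuple[int, str]]]:
    """Per output base, the window offset it derives from (or ``_PAD``),
    plus the alt-base overlay ``[(output index, alt character), ...]``.

    The plan drives track re-alignment (values follow positions); the
    overlay carries the substituted/inserted letters, which only the
    sequence path needs. This single routine is the source of truth for
    both, so sequence/track consistency is structural.
    """
    if target_length < 0:
        raise InvalidInputError("target_length must be non-negative")
    last = -1
    for v in variants:
        if v.pos < last:
            raise InvalidInputError("variant list must be sorted by position")
        last = v.pos

    plan = np.empty(target_length, dtype=np.int64)
    overlay: list[tuple[int, str]] = []
    out = 0  # bases emitted
    cursor = 0  # window offset of next unconsumed reference base

    def emit_ref(upto: int) -> None:
        nonlocal out, cursor
        upto = min(upto, window_len)
        if upto > cursor:
            n = min(upto - cursor, target_length - out)
            plan[out : out + n] = np.arange(cursor, cursor + n)
            out += n
        cursor = max(cursor, upto)

    for v in variants:
        if out >= target_length:
            break
        rel = v.pos - window_start
        if rel < cursor:
            if rel + len(v.ref) > cursor and rel >= 0:
                # overlapped by an applied deletion: swallowed, skip
                continue
            if rel < 0:
                # spanning deletion from before the window: consume the
                # in-window REF portion, contribute no alt bases
                cursor = max(cursor, rel + len(v.ref))
                continue
            continue
        emit_ref(rel)
        if out >= target_length:
            break
        # alt bases: base j derives from anchor + min(j, len(ref) - 1), so a
        # substitution maps positionally and inserted bases repeat the anchor
        n_alt = min(len(v.alt), target_length - out)
        ref_span = len(v.ref)
        for j in range(n_alt):
            src = rel + min(j, ref_span - 1)
            plan[out] = src if src < window_len else _PAD
            overlay.append((out, v.alt[j]))
            out += 1
        cursor = max(cursor, rel + ref_span)

    emit_ref(window_len)
    if out < target_length:
        plan[out:] = _PAD
    return plan, overlay


def reconstruct_haplotype(
    ref_window: np.ndarray | bytes | str,
    variants: Sequence[VariantRecord],
    target_length: int,
    window_start: int = 0,
) -> HaplotypeResult:
    """Splice one haplotype's alleles into the reference window.

    ``ref_window`` covers ``[window_start, window_start + len(window))`` on
    the reference; ``variants`` are this haplotype's pos-sorted,
    non-overlapping records clipped to the window. The output has exactly
    ``target_length`` bases, N-padded only if the window is exhausted.
    """
    window = _as_byte_array(ref_window)
    plan, overlay = _edit_plan(window.size, window_start, variants, target_length)
    sequence = np.full(target_length, b"N", dtype="S1")
    live = plan >= 0
    sequence[live] = window[plan[live]]
    for i, base in overlay:
        sequence[i] = base.encode("ascii")
    source_map = np.where(live, plan + window_start, 0).astype(np.int64)
    if not live.all():
        # padded entries inherit the last real source to keep the map monotone
        source_map[~live] = (
            source_map[live][-1] if live.any() else window_start
        )
    return HaplotypeResult(sequence=sequence, source_map=source_map)


def realign_track(
    per_base_values: np.ndarray,
    variants: Sequence[VariantRecord],
    target_length: int,
    window_start: int = 0,
) -> np.ndarray:
    """Re-align per-base reference values onto one haplotype's coordinates.

    Deleted positions are skipped, inserted bases duplicate their anchor's
    value, substitutions keep their value; padded positions (exhausted
    window) get 0.0. ``per_base_values`` must cover the same window passed
    to :func:`reconstruct_haplotype`.
    """
    values = np.asarray(per_base_values, dtype=np.float32)
    plan, _overlay = _edit_plan(values.size, window_start, variants, target_length)
    out = np.zeros(target_length, dtype=np.float32)
    live = plan >= 0
    out[live] = values[plan[live]]
    return out


def intervals_to_values(
    starts: np.ndarray,
    ends: np.ndarray,
    values: np.ndarray,
    window_start: int,
    window_length: int,
) -> np.ndarray:
    """Decode ``(start, end, value)`` runs to per-base values over a window.

    The runs must tile ``[window_start, window_start + window_length)``
    contiguously; a gap or short tiling raises :class:`CorruptStoreError`.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    values = np.asarray(values, dtype=np.float32)
    window_end = window_start + window_length
    if window_length == 0:
        return np.empty(0, dtype=np.float32)
    if starts.size == 0:
        raise CorruptStoreError("no runs cover the requested window")
    if np.any(starts[1:] != ends[:-1]):
        raise CorruptStoreError("interval runs are not contiguous")
    if starts[0] > window_start or ends[-1] < window_end:
        raise CorruptStoreError(
            f"runs [{starts[0]}, {ends[-1]}) do not cover window "
            f"[{window_start}, {window_end})"
        )
    clipped = np.minimum(ends, window_end) - np.maximum(starts, window_start)
    clipped = np.maximum(clipped, 0)
    return np.repeat(values, clipped)


def project_coordinate(
    ref_pos: int,
    variants: Sequence[VariantRecord],
    window_start: int = 0,
    window_end: int | None = None,
) -> int:
    """Offset of a reference position in the personalized haplotype.

    ``offset = (ref_pos - window_start) + sum(size_delta)`` over variants
    wholly left of ``ref_pos``. A position inside a deleted span maps to the
    offset of the deletion's anchor base. Monotone non-decreasing in
    ``ref_pos``.
    """
    if ref_pos < window_start or (window_end is not None and ref_pos >= window_end):
        raise InvalidInputError(
            f"reference position {ref_pos} outside window starting at {window_start}"
        )
    shift = 0
    for v in variants:
        if v.ref_end <= ref_pos:
            if v.pos >= window_start:
                shift += v.size_delta
            else:
                # spanning deletion: in-window REF bases removed, no alt kept
                shift -= v.ref_end - window_start
        elif v.pos < ref_pos:
            # inside this variant's REF span: a deletion removed this base;
            # return the offset of the surviving anchor base
            if v.pos < window_start:
                return 0
            return project_coordinate(v.pos, variants, window_start, window_end)
        else:
            break
    return (ref_pos - window_start) + shift


_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def reverse_complement(sequence: np.ndarray) -> np.ndarray:
    seq_bytes = sequence.tobytes().translate(_COMPLEMENT)
    return np.frombuffer(seq_bytes, dtype="S1")[::-1].copy()


def orient(result, strand: str):
    """Apply strand orientation: ``+`` is identity; ``-`` reverse-complements
    sequences (within a :class:`HaplotypeResult`, also reversing the source
    map) and reverses plain value vectors."""
    if strand not in ("+", "-"):
        raise InvalidInputError(f"strand must be '+' or '-', got {strand!r}")
    if strand == "+":
        return result
    if isinstance(result, HaplotypeResult):
        return HaplotypeResult(
            sequence=reverse_complement(result.sequence),
            source_map=result.source_map[::-1].copy(),
        )
    arr = np.asarray(result)
    if arr.dtype.kind == "S":
        return reverse_complement(arr)
    return arr[::-1].copy()


def _as_byte_array(seq) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq.astype("S1") if seq.dtype != np.dtype("S1") else seq
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return np.frombuffer(bytes(seq).upper(), dtype="S1")
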