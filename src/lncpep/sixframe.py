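"""Six-frame in silico translation with exact amino-acid <-> nucleotide bookkeeping.

Each transcript yields six reading frames: +1/+2/+3 read the stored sequence
at offsets 0/1/2, -1/-2/-3 read the reverse complement at the same offsets.
Stops are kept in the translation as '*'; downstream matching is restricted
to the maximal stop-free segments, since a presented peptide cannot span a
stop codon.

Translation uses a vectorized codon lookup built from the standard genetic
code; codons containing N translate to 'X', which matches no peptide residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio.Data import CodonTable

from .io import TranscriptRecord

FRAME_IDS = (1, 2, 3, -1, -2, -3)

_ENTRY_SEP = "|frame="

# --- codon lookup tables ----------------------------------------------------

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i
_BASE_CODE[ord("N")] = 4
_BASE_CODE[ord("n")] = 4

_COMPLEMENT = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTNacgtn", b"TGCANtgcan"):
    _COMPLEMENT[_a] = _b


def _build_aa64() -> np.ndarray:
    table = CodonTable.unambiguous_dna_by_id[1]  # the standard genetic code
    aa = np.zeros(64, dtype=np.uint8)
    bases = "ACGT"
    for i in range(64):
        codon = bases[i >> 4] + bases[(i >> 2) & 3] + bases[i & 3]
        if codon in table.stop_codons:
            aa[i] = ord("*")
        else:
            aa[i] = ord(table.forward_table[codon])
    return aa


_AA64 = _build_aa64()


def _encode(sequence: str) -> np.ndarray:
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _BASE_CODE[arr]
    if (codes == 255).any():
        bad = sorted({chr(b) for b in arr[codes == 255]})
        raise ValueError(f"unsupported nucleotide codes {bad}")
    return codes


def _translate_codes(codes: np.ndarray) -> str:
    n = len(codes) // 3
    if n == 0:
        return ""
    c = codes[: 3 * n].reshape(n, 3)
    valid = (c < 4).all(axis=1)
    idx = (c[:, 0].astype(np.int16) << 4) | (c[:, 1] << 2) | c[:, 2]
    idx[~valid] = 0
    aa = _AA64[idx]
    aa[~valid] = ord("X")
    return aa.tobytes().decode("ascii")


def translate(sequence: str) -> str:
    """Translate a nucleotide string in frame +1, dropping trailing 1-2 nt."""
    return _translate_codes(_encode(sequence))


def reverse_complement(sequence: str) -> str:
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _COMPLEMENT[arr][::-1].tobytes().decode("ascii")


# --- frame translations -----------------------------------------------------


@dataclass
class FrameTranslation:
    """One of six translated frames of a transcript.

    ``aa_sequence`` keeps '*' at stops; ``segments`` lists the maximal
    stop-free runs as (aa_start_in_frame, segment_string).
    """

    transcript_id: str
    frame_id: int
    aa_sequence: str
    nt_length: int

    @cached_property
    def segments(self) -> tuple[tuple[int, str], ...]:
        out = []
        pos = 0
        for piece in self.aa_sequence.split("*"):
            if piece:
                out.append((pos, piece))
            pos += len(piece) + 1
        return tuple(out)

    @property
    def entry_id(self) -> str:
        return f"{self.transcript_id}{_ENTRY_SEP}{self.frame_id:+d}"


def parse_entry_id(entry_id: str) -> tuple[str, int]:
    transcript_id, _, frame = entry_id.rpartition(_ENTRY_SEP)
    if not transcript_id:
        raise ValueError(f"not a translated-DB entry ID: {entry_id!r}")
    return transcript_id, int(frame)


def frame_offset(frame_id: int) -> int:
    if frame_id not in FRAME_IDS:
        raise ValueError(f"frame_id must be one of {FRAME_IDS}, got {frame_id}")
    return abs(frame_id) - 1


def translate_six_frames(sequence: str) -> list[FrameTranslation]:
    """Translate ``sequence`` in all six frames (standard genetic code).

    Reverse frames translate the reverse complement; the trailing 1-2 nt of
    each frame that do not fill a codon are dropped.
    """
    if len(sequence) < 3:
        raise ValueError(f"sequence shorter than one codon (length {len(sequence)})")
    fwd = _encode(sequence)
    rev = _encode(reverse_complement(sequence))
    out = []
    for frame_id in FRAME_IDS:
        codes = fwd if frame_id > 0 else rev
        off = frame_offset(frame_id)
        out.append(
            FrameTranslation(
                transcript_id="",
                frame_id=frame_id,
                aa_sequence=_translate_codes(codes[off:]),
                nt_length=len(sequence),
            )
        )
    return out


def iter_translated_db(
    transcripts: Iterable[TranscriptRecord | tuple[str, str]],
) -> Iterator[FrameTranslation]:
    """Yield the six frame translations of each transcript, streaming."""
    empty = True
    for t in transcripts:
        empty = False
        if isinstance(t, TranscriptRecord):
            tid, seq = t.transcript_id, t.sequence
        else:
            tid, seq = t
        try:
            frames = translate_six_frames(seq)
        except ValueError as exc:
            raise ValueError(f"{tid}: {exc}") from exc
        for fr in frames:
            fr.transcript_id = tid
            yield fr
    if empty:
        raise ValueError("empty transcript list: nothing to translate")


def build_translated_db(
    transcripts: Sequence[TranscriptRecord | tuple[str, str]],
) -> list[FrameTranslation]:
    """Six-frame translate a transcript set (6 entries per transcript)."""
    return list(iter_translated_db(transcripts))


def write_translated_fasta(path, db: Iterable[FrameTranslation]) -> None:
    with open(path, "w") as fh:
        for fr in db:
            fh.write(f">{fr.entry_id}\n")
            seq = fr.aa_sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# --- coordinate bookkeeping -------------------------------------------------


def frame_aa_length(frame_id: int, transcript_len: int) -> int:
    return (transcript_len - frame_offset(frame_id)) // 3


def aa_to_nt_interval(
    frame_id: int, aa_start: int, aa_len: int, transcript_len: int
) -> tuple[int, int]:
    """Map an amino-acid window of a frame to the transcript's stored-orientation
    nucleotide interval (0-based half-open).

    Forward frames count from the 5' end of the stored sequence; reverse
    frames read the reverse complement, so their windows are mirrored back
    onto the stored orientation.
    """
    if aa_len <= 0 or aa_start < 0:
        raise ValueError("amino-acid window must be non-empty and non-negative")
    if aa_start + aa_len > frame_aa_length(frame_id, transcript_len):
        raise ValueError(
            f"aa window [{aa_start}, {aa_start + aa_len}) exceeds frame {frame_id:+d} "
            f"of a {transcript_len}-nt transcript"
        )
    off = frame_offset(frame_id)
    if frame_id > 0:
        nt_start = off + 3 * aa_start
        return nt_start, nt_start + 3 * aa_len
    nt_start = transcript_len - off - 3 * (aa_start + aa_len)
    return nt_start, nt_start + 3 * aa_len
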