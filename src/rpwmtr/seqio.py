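"""Sequence and interval I/O.

DNA is carried everywhere as an :class:`EncodedSequence`: a numpy array of
integer codes with a→1, t→2, c→3, g→4.  All dynamic programming, statistics
and simulation operate on these codes; strings exist only at the I/O border.

IUPAC ambiguity codes are resolved to a concrete base drawn uniformly from
the code's allowed set, with a dedicated, reproducible seed.  Long runs of
ambiguous bases (assembly gaps) split a record into separately scanned
segments so that imputed sequence can never span a gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

#: nucleotide → integer code used throughout the package
CODE_OF = {"a": 1, "t": 2, "c": 3, "g": 4}
#: integer code → nucleotide
BASE_OF = {v: k for k, v in CODE_OF.items()}

# IUPAC ambiguity codes and the concrete codes they may stand for
_AMBIGUITY = {
    "r": (1, 4),        # a/g
    "y": (3, 2),        # c/t
    "s": (4, 3),        # g/c
    "w": (1, 2),        # a/t
    "k": (4, 2),        # g/t
    "m": (1, 3),        # a/c
    "b": (3, 4, 2),
    "d": (1, 4, 2),
    "h": (1, 3, 2),
    "v": (1, 3, 4),
    "n": (1, 2, 3, 4),
}

#: ambiguity runs longer than this split a record into separate segments
DEFAULT_SPLIT_RUN = 50


@dataclass
class EncodedSequence:
    """A DNA sequence as integer codes in {1, 2, 3, 4}.

    ``offset`` records the 0-based position of this segment within its
    source record (non-zero only for segments produced by gap splitting).
    """

    id: str
    codes: np.ndarray
    offset: int = 0

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 1 or self.codes.size == 0:
            raise ValueError("sequence must be a non-empty 1-D code array")
        if self.codes.min() < 1 or self.codes.max() > 4:
            raise ValueError("codes must lie in {1,2,3,4}")

    def __len__(self) -> int:
        return int(self.codes.size)

    def window(self, start: int, length: int) -> np.ndarray:
        """Codes of the window starting at 0-based ``start``."""
        return self.codes[start : start + length]

    @property
    def composition(self) -> np.ndarray:
        """Mononucleotide probabilities p(a), p(t), p(c), p(g)."""
        counts = np.bincount(self.codes, minlength=5)[1:5]
        return counts / counts.sum()


def encode_sequence(text: str, id: str = "seq", ambiguity_seed: int = 0) -> EncodedSequence:
    """Encode a DNA string, resolving IUPAC ambiguity codes at random.

    Raises ``ValueError`` on empty input or a non-IUPAC character (the
    error names the offending 1-based position).
    """
    if not text:
        raise ValueError("empty sequence")
    lowered = text.lower()
    codes = np.empty(len(lowered), dtype=np.int8)
    rng: np.random.Generator | None = None
    for i, ch in enumerate(lowered):
        c = CODE_OF.get(ch)
        if c is None:
            choices = _AMBIGUITY.get(ch)
            if choices is None:
                raise ValueError(f"non-IUPAC character {ch!r} at position {i + 1}")
            if rng is None:
                rng = np.random.default_rng(ambiguity_seed)
            c = choices[rng.integers(len(choices))]
        codes[i] = c
    return EncodedSequence(id=id, codes=codes)


def decode_sequence(seq: EncodedSequence | np.ndarray) -> str:
    codes = seq.codes if isinstance(seq, EncodedSequence) else np.asarray(seq)
    return "".join(BASE_OF[int(c)] for c in codes)


def shuffle_sequence(seq: EncodedSequence, seed: int) -> EncodedSequence:
    """Uniform random permutation of the sequence (composition preserved)."""
    rng = np.random.default_rng(seed)
    return EncodedSequence(id=f"{seq.id}|shuffle", codes=rng.permutation(seq.codes),
                           offset=seq.offset)


def _split_segments(text: str, split_run: int) -> list[tuple[int, str]]:
    """Split on runs of > ``split_run`` ambiguous bases; yield (offset, chunk)."""
    segments: list[tuple[int, str]] = []
    lowered = text.lower()
    i = 0
    start = 0
    L = len(lowered)
    while i < L:
        if lowered[i] in _AMBIGUITY:
            j = i
            while j < L and lowered[j] in _AMBIGUITY:
                j += 1
            if j - i > split_run:
                if i > start:
                    segments.append((start, text[start:i]))
                start = j
            i = j
        else:
            i += 1
    if L > start:
        segments.append((start, text[start:L]))
    return segments


def read_fasta(path, ambiguity_seed: int = 0,
               split_run: int = DEFAULT_SPLIT_RUN) -> list[EncodedSequence]:
    """Read a FASTA file into encoded sequences.

    Record ids are the first whitespace-delimited header token.  Runs of
    more than ``split_run`` ambiguous bases split a record into segments
    (ids unchanged, ``offset`` set); shorter runs are imputed at random
    with ``ambiguity_seed``.
    """
    out: list[EncodedSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        text = str(rec.seq)
        if not text:
            raise ValueError(f"empty FASTA record {rec.id!r}")
        for k, (off, chunk) in enumerate(_split_segments(text, split_run)):
            enc = encode_sequence(chunk, id=rec.id,
                                  ambiguity_seed=ambiguity_seed + k)
            enc.offset = off
            out.append(enc)
    return out


def write_fasta(path, sequences: list[EncodedSequence], width: int = 70) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            text = decode_sequence(seq)
            for i in range(0, len(text), width):
                fh.write(text[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Region tables.  TSV is 1-based inclusive; BED6 is 0-based half-open.

TSV_COLUMNS = ("seq_id", "start", "end", "period_n", "mFmax", "Z", "consensus")


def write_regions_tsv(path, regions, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for r in regions:
            z = "" if r.z is None else f"{r.z:.3f}"
            fh.write(f"{r.seq_id}\t{r.start + 1}\t{r.end}\t{r.n}\t"
                     f"{r.mfmax:.1f}\t{z}\t{r.consensus}\n")


def write_regions_bed(path, regions, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for r in regions:
            fh.write(f"{r.seq_id}\t{r.start}\t{r.end}\tTR_n{r.n}\t"
                     f"{round(r.mfmax)}\t+\n")
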