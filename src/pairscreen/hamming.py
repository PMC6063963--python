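"""Quaternary Hamming (SECDED-style) DNA barcodes.

A barcode is a fixed-length DNA word over {A,C,G,T} interpreted as digits
mod 4. The default 15-nt layout carries ten data bases, four checksum bases
at the power-of-two positions 1, 2, 4, 8 (each covering the data positions
whose 1-based index shares that bit), and one overall parity base at
position 15 covering positions 1-14. Check and parity digits are chosen so
that every covered sum is congruent to 0 (mod 4), which makes a received
word valid exactly when its syndrome vanishes. The code has minimum
Hamming distance 3 and therefore corrects any single base substitution.

Barcode pools are filtered for synthesizability (homopolymer runs, GC
content) and can be subsampled to a set with guaranteed minimum pairwise
Levenshtein distance, so that barcodes remain distinguishable even under
small indels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import edlib
import numpy as np

from .dna import BASES, gc_fraction, max_homopolymer

__all__ = [
    "BarcodeSpec",
    "Barcode",
    "DecodeResult",
    "BarcodeFilters",
    "encode",
    "decode",
    "passes_filters",
    "generate_all",
    "subsample_min_distance",
    "SubsampleResult",
    "read_barcode_list",
    "write_barcode_list",
    "write_barcode_fasta",
    "read_barcode_fasta",
]


def _auto_check_positions(n_data: int) -> tuple[int, ...]:
    """Smallest set of power-of-two check positions covering n_data data bases."""
    r = 1
    while 2**r < n_data + r + 1:
        r += 1
    return tuple(2**i for i in range(r))


@dataclass(frozen=True)
class BarcodeSpec:
    """Layout of a quaternary Hamming barcode.

    Parameters
    ----------
    n_data:
        Number of data bases (default 10, giving 4**10 candidate words).
    base_order:
        Bijection between nucleotides and digits 0..3, given as a 4-letter
        string; ``base_order[d]`` is the nucleotide encoding digit ``d``.
    check_positions:
        1-based positions of the checksum bases. Defaults to the powers of
        two that cover ``n_data`` data bases.
    parity_position:
        1-based position of the overall parity base (defaults to the last
        position).
    """

    n_data: int = 10
    base_order: str = "ACGT"
    check_positions: tuple[int, ...] = None  # type: ignore[assignment]
    parity_position: int = None  # type: ignore[assignment]

    def __post_init__(self):
        if sorted(self.base_order) != list("ACGT"):
            raise ValueError(f"base_order must be a permutation of ACGT, got {self.base_order!r}")
        checks = self.check_positions or _auto_check_positions(self.n_data)
        total = self.n_data + len(checks) + 1
        parity = self.parity_position or total
        object.__setattr__(self, "check_positions", tuple(sorted(checks)))
        object.__setattr__(self, "parity_position", parity)
        special = set(self.check_positions) | {parity}
        if len(special) != len(checks) + 1:
            raise ValueError("check positions and parity position must be distinct")
        if not special <= set(range(1, total + 1)):
            raise ValueError("check/parity positions outside 1..total_length")
        data_positions = tuple(p for p in range(1, total + 1) if p not in special)
        object.__setattr__(self, "_data_positions", data_positions)
        object.__setattr__(self, "_syndrome_table", None)
        object.__setattr__(self, "_H", None)
        object.__setattr__(self, "_digit_map", {b: i for i, b in enumerate(self.base_order)})

    @property
    def total_length(self) -> int:
        return self.n_data + len(self.check_positions) + 1

    @property
    def n_check(self) -> int:
        return len(self.check_positions)

    @property
    def data_positions(self) -> tuple[int, ...]:
        return self._data_positions

    # --- digit-level machinery -------------------------------------------

    def _coverage(self, check: int) -> tuple[int, ...]:
        """Data positions covered by the check base at ``check`` (bit overlap)."""
        return tuple(p for p in self.data_positions if p & check)

    def encode_digits(self, words: np.ndarray) -> np.ndarray:
        """Encode an (n, n_data) array of digits into (n, total_length) codewords."""
        words = np.asarray(words)
        squeeze = words.ndim == 1
        words = np.atleast_2d(words)
        if words.shape[1] != self.n_data:
            raise ValueError(f"expected {self.n_data} data symbols, got {words.shape[1]}")
        if words.size and (words.min() < 0 or words.max() > 3):
            raise ValueError("data symbols must be in 0..3")
        code = np.zeros((words.shape[0], self.total_length), dtype=np.int8)
        for i, p in enumerate(self.data_positions):
            code[:, p - 1] = words[:, i]
        for c in self.check_positions:
            cov = [p - 1 for p in self._coverage(c)]
            code[:, c - 1] = (-code[:, cov].sum(axis=1)) % 4
        rest = [p for p in range(1, self.total_length + 1) if p != self.parity_position]
        code[:, self.parity_position - 1] = (-code[:, [p - 1 for p in rest]].sum(axis=1)) % 4
        return code[0] if squeeze else code

    def parity_check_matrix(self) -> np.ndarray:
        """(n_check+1, total_length) matrix H with H @ codeword == 0 (mod 4)."""
        if self._H is None:
            H = np.zeros((self.n_check + 1, self.total_length), dtype=np.int8)
            for row, c in enumerate(self.check_positions):
                H[row, c - 1] = 1
                for p in self._coverage(c):
                    H[row, p - 1] = 1
            H[-1, :] = 1  # parity row covers every position including itself
            object.__setattr__(self, "_H", H)
        return self._H

    def syndrome_table(self) -> dict[tuple, tuple[int, int]]:
        """Map syndrome -> (1-based position, error digit) for unique single errors.

        Syndromes shared by several single-substitution error patterns (possible
        only for degraded layouts with code distance < 3) are omitted, so lookup
        failure means "not correctable unambiguously".
        """
        if self._syndrome_table is None:
            H = self.parity_check_matrix()
            table: dict[tuple, tuple[int, int]] = {}
            clashes = set()
            for p in range(1, self.total_length + 1):
                for e in (1, 2, 3):
                    s = tuple((e * H[:, p - 1]) % 4)
                    if s in table or s in clashes:
                        table.pop(s, None)
                        clashes.add(s)
                    else:
                        table[s] = (p, e)
            object.__setattr__(self, "_syndrome_table", table)
        return self._syndrome_table

    # --- string <-> digit conversion -------------------------------------

    def to_digits(self, seq: str) -> Optional[np.ndarray]:
        try:
            return np.array([self._digit_map[b] for b in seq], dtype=np.int8)
        except KeyError:
            return None

    def to_sequence(self, digits: np.ndarray) -> str:
        return "".join(self.base_order[int(d)] for d in digits)

    def extract_data(self, digits: np.ndarray) -> tuple[int, ...]:
        return tuple(int(digits[p - 1]) for p in self.data_positions)


DEFAULT_SPEC = BarcodeSpec()


class Barcode(NamedTuple):
    sequence: str
    data_word: tuple[int, ...]
    member_id: Optional[int] = None


@dataclass(frozen=True)
class DecodeResult:
    status: str  # "exact" | "corrected" | "fail"
    data_word: Optional[tuple[int, ...]] = None
    corrected_position: Optional[int] = None
    reason: Optional[str] = None

    def __post_init__(self):
        if self.status == "exact" and self.corrected_position is not None:
            raise ValueError("exact decode cannot carry a corrected position")
        if self.status == "fail" and self.data_word is not None:
            raise ValueError("failed decode cannot carry a data word")


def encode(data_word: Sequence[int], spec: BarcodeSpec = DEFAULT_SPEC) -> Barcode:
    """Encode a quaternary data word into a DNA barcode."""
    word = tuple(int(s) for s in data_word)
    if len(word) != spec.n_data:
        raise ValueError(f"data word must have {spec.n_data} symbols, got {len(word)}")
    if any(s < 0 or s > 3 for s in word):
        raise ValueError(f"data symbols must be in 0..3, got {word}")
    digits = spec.encode_digits(np.array(word, dtype=np.int8))
    return Barcode(sequence=spec.to_sequence(digits), data_word=word)


def decode(observed: str, spec: BarcodeSpec = DEFAULT_SPEC) -> DecodeResult:
    """Decode an observed DNA word, correcting at most one substitution.

    Syndrome lookup: a valid codeword has zero syndrome; a single
    substitution of digit ``e`` at position ``p`` produces the syndrome
    ``e * H[:, p]``, which for the default distance-3 layout identifies
    ``(p, e)`` uniquely. Anything else (two or more errors, ambiguous
    syndromes of degraded toy layouts, non-ACGT symbols, wrong length)
    fails rather than guessing.
    """
    if len(observed) != spec.total_length:
        return DecodeResult("fail", reason=f"expected length {spec.total_length}, got {len(observed)}")
    digits = spec.to_digits(observed)
    if digits is None:
        return DecodeResult("fail", reason="non-ACGT symbol")
    H = spec.parity_check_matrix()
    syndrome = tuple((H @ digits) % 4)
    if not any(syndrome):
        return DecodeResult("exact", data_word=spec.extract_data(digits))
    hit = spec.syndrome_table().get(syndrome)
    if hit is None:
        return DecodeResult("fail", reason="uncorrectable syndrome")
    pos, err = hit
    digits = digits.copy()
    digits[pos - 1] = (digits[pos - 1] - err) % 4
    return DecodeResult("corrected", data_word=spec.extract_data(digits), corrected_position=pos)


@dataclass(frozen=True)
class BarcodeFilters:
    """Synthesizability filters: homopolymer runs and GC content (inclusive bounds)."""

    max_homopolymer: int = 3
    gc_min: float = 0.30
    gc_max: float = 0.70


def passes_filters(
    sequence: str,
    max_homopolymer_len: int = 3,
    gc_min: float = 0.30,
    gc_max: float = 0.70,
) -> bool:
    """True iff the longest homopolymer run and GC fraction are within bounds."""
    if not sequence or any(b not in BASES for b in sequence):
        return False
    if max_homopolymer(sequence) > max_homopolymer_len:
        return False
    return gc_min <= gc_fraction(sequence) <= gc_max


def generate_all(
    spec: BarcodeSpec = DEFAULT_SPEC,
    filters: Optional[BarcodeFilters] = BarcodeFilters(),
) -> list[Barcode]:
    """Enumerate every data word, encode it, and keep barcodes passing filters.

    The enumeration is fully vectorised (the default spec encodes all
    4**10 = 1,048,576 candidates in a few seconds) and the output is sorted
    by data word, so the result is identical across runs and platforms.
    """
    n = 4**spec.n_data
    words = np.indices((4,) * spec.n_data).reshape(spec.n_data, -1).T.astype(np.int8)
    code = spec.encode_digits(words)
    letters = np.frombuffer(spec.base_order.encode(), dtype=np.uint8)
    seqs = letters[code]
    keep = np.ones(n, dtype=bool)
    if filters is not None:
        total = spec.total_length
        gc = ((seqs == ord("G")) | (seqs == ord("C"))).sum(axis=1)
        keep &= (gc >= filters.gc_min * total) & (gc <= filters.gc_max * total)
        if filters.max_homopolymer < total:
            eq = seqs[:, 1:] == seqs[:, :-1]
            k = filters.max_homopolymer
            run = eq[:, : total - k]
            for i in range(1, k):
                run = run & eq[:, i : total - k + i]
            keep &= ~run.any(axis=1)
    raw = seqs[keep].tobytes().decode("ascii")
    total = spec.total_length
    out = []
    kept_words = words[keep]
    for i in range(kept_words.shape[0]):
        out.append(Barcode(raw[i * total : (i + 1) * total], tuple(int(x) for x in kept_words[i])))
    return out


class SubsampleResult(NamedTuple):
    barcodes: list[Barcode]
    complete: bool  # False when n_target was unreachable at the requested distance
    message: str


def subsample_min_distance(
    barcodes: Sequence[Barcode],
    n_target: int,
    min_edit_distance: int = 3,
    seed: int = 0,
) -> SubsampleResult:
    """Greedily pick up to ``n_target`` barcodes at pairwise Levenshtein >= min_edit_distance.

    The candidate order is a seeded shuffle; each candidate is accepted iff its
    edit distance to every already-accepted barcode is at least the requested
    minimum (edlib with an early-exit distance bound). When the target count is
    unreachable the partial set is returned with ``complete=False``.
    """
    if n_target > len(barcodes):
        raise ValueError(f"n_target={n_target} exceeds pool size {len(barcodes)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(barcodes))
    accepted: list[Barcode] = []
    k = min_edit_distance - 1
    for idx in order:
        cand = barcodes[idx]
        ok = True
        for acc in accepted:
            res = edlib.align(cand.sequence, acc.sequence, task="distance", k=k)
            if res["editDistance"] != -1:  # distance <= k, too close
                ok = False
                break
        if ok:
            accepted.append(cand)
            if len(accepted) == n_target:
                return SubsampleResult(accepted, True, f"selected {n_target} barcodes")
    msg = (
        f"only {len(accepted)} of {n_target} requested barcodes reachable at "
        f"Levenshtein distance >= {min_edit_distance}"
    )
    return SubsampleResult(accepted, False, msg)


# --- plain-text / FASTA I/O ----------------------------------------------


def write_barcode_list(barcodes: Iterable[Barcode], path) -> None:
    with open(path, "w") as fh:
        for bc in barcodes:
            fh.write(bc.sequence + "\n")


def read_barcode_list(path, spec: BarcodeSpec = DEFAULT_SPEC) -> list[Barcode]:
    out = []
    with open(path) as fh:
        for line in fh:
            seq = line.strip()
            if not seq:
                continue
            digits = spec.to_digits(seq)
            if digits is None or len(seq) != spec.total_length:
                raise ValueError(f"invalid barcode line: {seq!r}")
            out.append(Barcode(seq, spec.extract_data(digits)))
    return out


def write_barcode_fasta(barcodes: Iterable[Barcode], path) -> None:
    with open(path, "w") as fh:
        for i, bc in enumerate(barcodes):
            ident = bc.member_id if bc.member_id is not None else i
            fh.write(f">{ident}\n{bc.sequence}\n")


def read_barcode_fasta(path, spec: BarcodeSpec = DEFAULT_SPEC) -> list[Barcode]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        digits = spec.to_digits(seq)
        if digits is None:
            raise ValueError(f"invalid barcode record {rec.id}")
        out.append(Barcode(seq, spec.extract_data(digits), member_id=int(rec.id)))
    return out
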