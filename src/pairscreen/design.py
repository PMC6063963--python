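"""Pairwise guide-target library design.

A library member couples one sgRNA spacer with one synthetic target-site
variant on a single lentiviral cassette. Spacers are organised in groups
sharing the 18 PAM-proximal bases (positions 1-18, counted from the PAM)
and varying in length from 19 to 24 nt by 5' extension; the 5'-most base is
always G for reliable U6-driven expression. Each spacer is paired with
target variants carrying systematic mismatches, bulges, or a scrambled
control, all against a constant 5'-CAGGGT-3' PAM. Every member receives a
unique error-correcting Hamming barcode placed downstream of the predicted
cut site so that the guide-target identity survives editing.

Position convention used throughout the package: position 1 is the
PAM-proximal base of the protospacer (the 3'-most base of the target as
written 5'->3'), so string index ``L - position`` addresses position
``position`` in a length-``L`` target.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .dna import BASES, TRANSVERSIONS, random_seq, revcomp
from .hamming import Barcode

__all__ = [
    "PAM",
    "SPACER_LENGTHS",
    "CassetteLayout",
    "SpacerGroup",
    "TargetVariant",
    "LibraryMember",
    "CATEGORIES",
    "generate_spacer_groups",
    "enumerate_variants",
    "assemble_library",
    "emit_oligos",
    "library_to_frame",
    "write_design",
    "read_design",
    "parse_oligo_header",
]

PAM = "CAGGGT"
SPACER_LENGTHS = tuple(range(19, 25))
CATEGORIES = (
    "matched",
    "single_mismatch",
    "double_mismatch",
    "double_transversion",
    "insertion",
    "deletion",
    "scrambled",
)


@dataclass(frozen=True)
class CassetteLayout:
    """Constant segments of the library cassette (sequenced strand, 5'->3').

    Order: prefix | spacer | scaffold5 | rBC (8 nt) | scaffold3 | target |
    PAM | post_pam | Hamming barcode | suffix. ``post_pam`` is sized so the
    barcode begins ``barcode_offset`` bp downstream of the predicted cut
    site (blunt cut ``cut_offset`` bp 5' of the PAM).
    """

    prefix: str = "CTTGTGGAAAGGACGAAACACC"
    scaffold5: str = "GTTTTAGTACTCTGGAAACAGAATC"
    scaffold3: str = "GGTGTTTCGTCCTTTCCACAAGAT"
    pam: str = PAM
    post_pam: str = "ATCGTAC"
    suffix: str = "ATCTCGTATGCCGTCTTCTGC"
    rbc_length: int = 8
    cut_offset: int = 3  # blunt cut this many bp 5' of the PAM
    barcode_offset: int = 16  # barcode starts this many bp downstream of the cut

    def __post_init__(self):
        gap = self.cut_offset + len(self.pam) + len(self.post_pam)
        if gap != self.barcode_offset:
            raise ValueError(
                f"cut-to-barcode gap {gap} != barcode_offset {self.barcode_offset}; "
                "resize post_pam"
            )

    def cassette(self, spacer: str, target: str, barcode: str, rbc: Optional[str] = None) -> str:
        rbc = rbc if rbc is not None else "N" * self.rbc_length
        if len(rbc) != self.rbc_length:
            raise ValueError(f"rBC must be {self.rbc_length} nt")
        return (
            self.prefix + spacer + self.scaffold5 + rbc + self.scaffold3
            + target + self.pam + self.post_pam + barcode + self.suffix
        )


@dataclass(frozen=True)
class SpacerGroup:
    group_id: int
    core18: str
    spacers: Mapping[int, str]  # length -> spacer, 5'->3'

    def __post_init__(self):
        for L, sp in self.spacers.items():
            if len(sp) != L:
                raise ValueError(f"group {self.group_id}: spacer {sp} is not {L} nt")
            if not sp.endswith(self.core18):
                raise ValueError(f"group {self.group_id}: spacer does not end with core18")
            if sp[0] != "G":
                raise ValueError(f"group {self.group_id}: spacer 5' base must be G")


@dataclass(frozen=True)
class TargetVariant:
    category: str
    positions: tuple[int, ...]  # 1-based PAM-proximal
    target_sequence: str
    pam: str = PAM
    multiplicity: int = 1

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown variant category {self.category!r}")


@dataclass(frozen=True)
class LibraryMember:
    member_id: int
    group_id: int
    spacer: str
    variant: TargetVariant
    barcode: Barcode

    @property
    def spacer_length(self) -> int:
        return len(self.spacer)

    @property
    def category(self) -> str:
        return self.variant.category

    @property
    def target(self) -> str:
        return self.variant.target_sequence

    def cassette(self, layout: CassetteLayout, rbc: Optional[str] = None) -> str:
        return layout.cassette(self.spacer, self.target, self.barcode.sequence, rbc)


# --- spacer groups --------------------------------------------------------


def _reference_contains(reference: Mapping[str, str], query: str) -> bool:
    rc = revcomp(query)
    return any(query in seq or rc in seq for seq in reference.values())


def load_reference_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def generate_spacer_groups(
    n_groups: int,
    seed: int,
    reference: Optional[Mapping[str, str]] = None,
    lengths: Sequence[int] = SPACER_LENGTHS,
    max_retries: int = 100,
) -> list[SpacerGroup]:
    """Seeded-random spacer groups, optionally orthogonal to a reference.

    Each group draws a random 24-nt sequence whose 18 PAM-proximal bases are
    the shared core; the length-``L`` spacer is its 3'-most ``L`` bases with
    the 5' base forced to G. When a reference is given, a group whose
    core18+PAM occurs in the reference (either strand) is rejected and
    redrawn, up to ``max_retries`` attempts per group.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if any(L < 19 or L > 24 for L in lengths):
        raise ValueError("spacer lengths must lie in 19..24")
    rng = np.random.default_rng(seed)
    groups = []
    for gid in range(n_groups):
        for _ in range(max_retries):
            full24 = random_seq(rng, 24)
            core18 = full24[-18:]
            if reference is not None and _reference_contains(reference, core18 + PAM):
                continue
            spacers = {L: "G" + full24[24 - L + 1 :] for L in sorted(lengths)}
            groups.append(SpacerGroup(gid, core18, spacers))
            break
        else:
            raise RuntimeError(
                f"could not draw a reference-orthogonal core for group {gid} "
                f"after {max_retries} attempts"
            )
    return groups


# --- target variants ------------------------------------------------------


def _sub(target: str, idx: int, base: str) -> str:
    return target[:idx] + base + target[idx + 1 :]


def _dedupe(cands: list[tuple[tuple[int, ...], str]], category: str) -> list[TargetVariant]:
    """Collapse identical sequences (e.g. indels in homopolymer runs)."""
    seen: dict[str, TargetVariant] = {}
    for positions, seq in cands:
        if seq in seen:
            v = seen[seq]
            seen[seq] = replace(v, multiplicity=v.multiplicity + 1)
        else:
            seen[seq] = TargetVariant(category, positions, seq)
    return list(seen.values())


def enumerate_variants(
    spacer: str,
    categories: Iterable[str],
    seed: int = 0,
    n_scrambled: int = 1,
) -> list[TargetVariant]:
    """All target variants of the requested categories for one spacer.

    Counts before deduplication: 3L single mismatches, 9*C(L,2) double
    mismatches, 4*C(L,2) double transversions (each position takes one of
    its two transversion partners), 4*(L+1) insertions, L deletions.
    Identical sequences arising from indels within homopolymer runs are
    collapsed with their multiplicity recorded.
    """
    L = len(spacer)
    if L not in SPACER_LENGTHS:
        raise ValueError(f"spacer length {L} outside 19..24")
    categories = list(categories)
    unknown = set(categories) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    out: list[TargetVariant] = []
    matched = spacer  # protospacer strand identical to the spacer (U->T)

    def pos2idx(pos: int) -> int:
        return L - pos

    for category in categories:
        if category == "matched":
            out.append(TargetVariant("matched", (), matched))
        elif category == "single_mismatch":
            for pos in range(1, L + 1):
                i = pos2idx(pos)
                for b in BASES:
                    if b != matched[i]:
                        out.append(TargetVariant("single_mismatch", (pos,), _sub(matched, i, b)))
        elif category == "double_mismatch":
            for p1 in range(1, L):
                for p2 in range(p1 + 1, L + 1):
                    i1, i2 = pos2idx(p1), pos2idx(p2)
                    for b1 in BASES:
                        if b1 == matched[i1]:
                            continue
                        for b2 in BASES:
                            if b2 == matched[i2]:
                                continue
                            seq = _sub(_sub(matched, i1, b1), i2, b2)
                            out.append(TargetVariant("double_mismatch", (p1, p2), seq))
        elif category == "double_transversion":
            for p1 in range(1, L):
                for p2 in range(p1 + 1, L + 1):
                    i1, i2 = pos2idx(p1), pos2idx(p2)
                    for b1 in TRANSVERSIONS[matched[i1]]:
                        for b2 in TRANSVERSIONS[matched[i2]]:
                            seq = _sub(_sub(matched, i1, b1), i2, b2)
                            out.append(TargetVariant("double_transversion", (p1, p2), seq))
        elif category == "insertion":
            cands = []
            for i in range(L + 1):  # insert before string index i
                for b in BASES:
                    # PAM-proximal slot: 0 = between target and PAM
                    cands.append(((L - i,), matched[:i] + b + matched[i:]))
            out.extend(_dedupe(cands, "insertion"))
        elif category == "deletion":
            cands = [((L - i,), matched[:i] + matched[i + 1 :]) for i in range(L)]
            out.extend(_dedupe(cands, "deletion"))
        elif category == "scrambled":
            rng = np.random.default_rng(seed)
            made = 0
            attempts = 0
            while made < n_scrambled and attempts < 1000:
                attempts += 1
                perm = rng.permutation(L)
                seq = "".join(matched[i] for i in perm)
                diff = sum(a != b for a, b in zip(seq, matched))
                if diff >= L / 2:
                    out.append(TargetVariant("scrambled", (), seq))
                    made += 1
            if made < n_scrambled:
                raise RuntimeError("could not scramble target away from spacer")
    return out


# --- library assembly -----------------------------------------------------


def assemble_library(
    groups: Sequence[SpacerGroup],
    variant_plan: Mapping[int, Sequence[str]],
    barcodes: Sequence[Barcode],
    seed: int,
) -> list[LibraryMember]:
    """Pair every planned variant with a unique Hamming barcode.

    ``variant_plan`` maps group_id to the variant categories requested for
    that group (applied to every spacer length in the group). Barcodes are
    assigned by a seeded shuffle; running out of barcodes is an error naming
    the shortfall.
    """
    rng = np.random.default_rng(seed)
    members_wo_bc: list[tuple[int, str, TargetVariant]] = []
    for group in groups:
        cats = variant_plan.get(group.group_id)
        if not cats:
            continue
        for L in sorted(group.spacers):
            spacer = group.spacers[L]
            scramble_seed = int(rng.integers(0, 2**31 - 1))
            for variant in enumerate_variants(spacer, cats, seed=scramble_seed):
                members_wo_bc.append((group.group_id, spacer, variant))
    n = len(members_wo_bc)
    if n > len(barcodes):
        raise ValueError(
            f"library needs {n} barcodes but only {len(barcodes)} supplied "
            f"(short by {n - len(barcodes)})"
        )
    order = rng.permutation(len(barcodes))[:n]
    members = []
    for mid, ((gid, spacer, variant), bi) in enumerate(zip(members_wo_bc, order)):
        bc = barcodes[int(bi)]._replace(member_id=mid)
        members.append(LibraryMember(mid, gid, spacer, variant, bc))
    return members


def uniform_plan(groups: Sequence[SpacerGroup], categories: Sequence[str]) -> dict[int, tuple[str, ...]]:
    return {g.group_id: tuple(categories) for g in groups}


# --- serialization --------------------------------------------------------

_HEADER_RE = re.compile(r"^m(?P<member>\d+)\|g(?P<group>\d+)\|(?P<category>\w+)\|L(?P<length>\d+)$")


def oligo_header(member: LibraryMember) -> str:
    return f"m{member.member_id}|g{member.group_id}|{member.category}|L{member.spacer_length}"


def parse_oligo_header(header: str) -> dict:
    m = _HEADER_RE.match(header)
    if not m:
        raise ValueError(f"not a library oligo header: {header!r}")
    d = m.groupdict()
    return {
        "member_id": int(d["member"]),
        "group_id": int(d["group"]),
        "category": d["category"],
        "spacer_length": int(d["length"]),
    }


def emit_oligos(
    library: Sequence[LibraryMember],
    path,
    layout: CassetteLayout = CassetteLayout(),
    length_window: Optional[tuple[int, int]] = None,
) -> None:
    """Write one FASTA record per member (cassette with rBC placeholder).

    With ``length_window`` set, any member whose oligo falls outside the
    window aborts the emission with a message listing the offenders.
    """
    records = [(oligo_header(m), m.cassette(layout)) for m in library]
    if length_window is not None:
        lo, hi = length_window
        bad = [h for h, s in records if not lo <= len(s) <= hi]
        if bad:
            raise ValueError(f"{len(bad)} oligos outside length window {length_window}: {bad[:10]}")
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n{seq}\n")


def library_to_frame(library: Sequence[LibraryMember]) -> pd.DataFrame:
    rows = [
        {
            "member_id": m.member_id,
            "group_id": m.group_id,
            "spacer": m.spacer,
            "spacer_length": m.spacer_length,
            "category": m.category,
            "positions": ",".join(map(str, m.variant.positions)),
            "target": m.target,
            "pam": m.variant.pam,
            "barcode": m.barcode.sequence,
            "multiplicity": m.variant.multiplicity,
        }
        for m in library
    ]
    return pd.DataFrame(rows)


def write_design(library: Sequence[LibraryMember] | pd.DataFrame, path) -> None:
    df = library if isinstance(library, pd.DataFrame) else library_to_frame(library)
    df.to_csv(path, sep="\t", index=False)


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"positions": str}, keep_default_na=False)
    df["positions"] = df["positions"].fillna("")
    return df
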