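"""Read-level quantification of the pairwise screen.

Paired-end cassette reads are parsed against the cassette layout (constant
anchors locate the spacer, rBC, target region and Hamming barcode), the
barcode is decoded with single-substitution correction to identify the
library member, Day-0 reads build a whitelist of error-free (member, rBC)
cassettes, and later timepoints yield per-member indel rates computed from
whitelisted rBCs only. Substitution-only changes in the target region are
discarded rather than called, since Cas9 repair products are indels, not
point changes; indels are only counted when they overlap a window around
the predicted cut site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy import stats

from . import hamming
from .design import CassetteLayout
from .dna import revcomp

__all__ = [
    "DesignIndex",
    "IndelPolicy",
    "parse_read_pair",
    "parse_fastq_pair",
    "build_whitelist",
    "call_indel",
    "compute_indel_rates",
    "off_on_ratios",
    "aggregate_tolerance",
    "replicate_concordance",
    "find_approx",
]


class DesignIndex:
    """Lookup tables over a design frame: barcode -> member, member -> row.

    ``expected_region(member)`` is the designed sequence of the compared
    window on read 2: target + PAM + post-PAM constant, i.e. everything
    between the scaffold anchor and the Hamming barcode. Comparing the
    whole window keeps deletions that chew into the PAM visible to the
    indel caller.
    """

    def __init__(
        self,
        design: pd.DataFrame,
        spec: hamming.BarcodeSpec = hamming.DEFAULT_SPEC,
        layout: CassetteLayout = CassetteLayout(),
    ):
        self.design = design.reset_index(drop=True)
        self.spec = spec
        self.layout = layout
        self.by_barcode = dict(zip(design["barcode"], design["member_id"].astype(int)))
        if len(self.by_barcode) != len(design):
            raise ValueError("barcodes are not unique across the design")
        self.by_member = {
            int(r.member_id): r for r in design.itertuples(index=False)
        }
        tail = layout.pam + layout.post_pam
        self._expected = {
            m: r.target + tail for m, r in self.by_member.items()
        }

    def member_for_barcode(self, sequence: str) -> Optional[int]:
        return self.by_barcode.get(sequence)

    def expected_region(self, member: int) -> str:
        return self._expected[member]


def find_approx(hay: str, needle: str, max_mismatch: int = 1) -> int:
    """Leftmost occurrence of needle in hay with at most max_mismatch
    substitutions; -1 when absent. Exact find is tried first."""
    pos = hay.find(needle)
    if pos >= 0 or max_mismatch == 0:
        return pos
    n = len(needle)
    for start in range(len(hay) - n + 1):
        mm = 0
        for a, b in zip(needle, hay[start : start + n]):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            return start
    return -1


def parse_read_pair(
    read1: str,
    read2: str,
    index: DesignIndex,
    layout: CassetteLayout = CassetteLayout(),
    max_anchor_mismatch: int = 1,
) -> dict:
    """Extract spacer, rBC, target region and decoded member from one read pair.

    Read 1 runs 5'->3' from the cassette start (spacer side); read 2 is the
    reverse-strand mate covering target, PAM and Hamming barcode. Read 2 is
    anchored on the scaffold (left) and the cassette suffix (right): the
    Hamming barcode sits at a fixed offset left of the suffix, and the
    compared target region is everything in between, so cut-site indels --
    even ones reaching into the PAM -- stay inside the compared window.
    Anchors are located allowing ``max_anchor_mismatch`` substitutions
    each; a read pair whose anchors cannot be located is returned with
    ``anchors_ok=False`` and counted, never silently dropped.
    """
    obs = {
        "member_id": pd.NA,
        "rbc": None,
        "spacer_obs": None,
        "target_obs": None,
        "anchors_ok": False,
        "hamming_status": "fail",
    }
    mm = max_anchor_mismatch
    bclen = index.spec.total_length
    p0 = find_approx(read1, layout.prefix, mm)
    p1 = find_approx(read1, layout.scaffold5, mm)
    tail = revcomp(read2)
    q0 = find_approx(tail, layout.scaffold3, mm)
    q1 = find_approx(tail, layout.suffix, mm)
    if p0 < 0 or p1 <= p0 or q0 < 0 or q1 < 0:
        return obs
    rbc_start = p1 + len(layout.scaffold5)
    rbc = read1[rbc_start : rbc_start + layout.rbc_length]
    region_start = q0 + len(layout.scaffold3)
    bc_start = q1 - bclen
    barcode = tail[bc_start:q1]
    if len(rbc) < layout.rbc_length or bc_start <= region_start:
        return obs
    obs["anchors_ok"] = True
    obs["rbc"] = rbc
    obs["spacer_obs"] = read1[p0 + len(layout.prefix) : p1]
    obs["target_obs"] = tail[region_start:bc_start]
    dec = hamming.decode(barcode, index.spec)
    obs["hamming_status"] = dec.status
    if dec.status != "fail":
        canonical = hamming.encode(dec.data_word, index.spec).sequence
        member = index.member_for_barcode(canonical)
        if member is not None:
            obs["member_id"] = member
        else:
            obs["hamming_status"] = "fail"  # valid codeword, but not in this library
    return obs


_OBS_COLUMNS = ["member_id", "rbc", "spacer_obs", "target_obs", "anchors_ok", "hamming_status"]


def parse_fastq_pair(
    r1_path,
    r2_path,
    index: DesignIndex,
    layout: CassetteLayout = CassetteLayout(),
    max_anchor_mismatch: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Parse paired FASTQ into an observation table plus read accounting."""
    import pysam

    rows = []
    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        for rec1, rec2 in zip(f1, f2):
            rows.append(
                parse_read_pair(rec1.sequence, rec2.sequence, index, layout, max_anchor_mismatch)
            )
    obs = pd.DataFrame(rows, columns=_OBS_COLUMNS)
    obs["member_id"] = obs["member_id"].astype("Int64")
    accounting = {
        "n_read_pairs": len(obs),
        "n_anchor_fail": int((~obs["anchors_ok"]).sum()),
        "n_hamming_exact": int((obs["hamming_status"] == "exact").sum()),
        "n_hamming_corrected": int((obs["hamming_status"] == "corrected").sum()),
        "n_hamming_fail": int((obs["hamming_status"] == "fail").sum()),
        "n_member_assigned": int(obs["member_id"].notna().sum()),
    }
    return obs, accounting


# --- whitelist ------------------------------------------------------------


def build_whitelist(
    day0_obs: pd.DataFrame,
    index: DesignIndex,
    min_reads_per_rbc: int = 2,
) -> pd.DataFrame:
    """Whitelist of (member, rBC) cassettes validated error-free at Day 0.

    A cassette is admitted iff every one of its supporting reads has intact
    anchors, an exactly matching Hamming barcode, and spacer and target
    regions that equal the designed sequences base-for-base, with read
    support of at least ``min_reads_per_rbc``. An rBC observed under more
    than one member is a conflict (template switching or barcode damage)
    and is rejected outright.
    """
    if day0_obs.empty:
        warnings.warn("empty Day-0 observation table; whitelist is empty")
        return pd.DataFrame(columns=["member_id", "rbc", "day0_read_count"])
    obs = day0_obs.copy()

    def read_valid(row) -> bool:
        if not row["anchors_ok"] or row["hamming_status"] != "exact" or pd.isna(row["member_id"]):
            return False
        member = int(row["member_id"])
        ref = index.by_member[member]
        return (
            row["spacer_obs"] == ref.spacer
            and row["target_obs"] == index.expected_region(member)
        )

    obs["valid"] = [read_valid(r) for _, r in obs.iterrows()]
    assigned = obs[obs["member_id"].notna()]
    conflicts = {
        rbc
        for rbc, grp in assigned.groupby("rbc")["member_id"]
        if grp.nunique() > 1
    }
    entries = []
    for (member, rbc), grp in assigned.groupby(["member_id", "rbc"]):
        if rbc in conflicts:
            continue
        if len(grp) >= min_reads_per_rbc and grp["valid"].all():
            entries.append(
                {"member_id": int(member), "rbc": rbc, "day0_read_count": len(grp)}
            )
    wl = pd.DataFrame(entries, columns=["member_id", "rbc", "day0_read_count"])
    return wl.sort_values(["member_id", "rbc"]).reset_index(drop=True)


# --- indel calling --------------------------------------------------------


@dataclass(frozen=True)
class IndelPolicy:
    """Cut-site geometry and calling rules.

    ``cut_from_3p`` is the distance of the blunt cut from the 3' end of the
    compared region. With the default region (target + PAM + 7-nt constant)
    and a cut 3 bp 5' of the PAM this is 3 + 6 + 7 = 16; when comparing
    bare target sequences use 3. An alignment indel counts as an edit only
    when it overlaps the cut +/- ``window`` bp. Equal-length observations
    explainable by substitutions alone are discarded (substitutions cannot
    be nuclease products), as are indels entirely outside the window.
    """

    window: int = 8
    cut_from_3p: int = 16


def call_indel(target_region: str, expected: str, policy: IndelPolicy = IndelPolicy()) -> str:
    """Classify one target-region observation: 'intact' | 'indel' | 'discard'."""
    if target_region == expected:
        return "intact"
    if not target_region:
        return "discard"
    if len(target_region) == len(expected):
        ham = sum(a != b for a, b in zip(target_region, expected))
        d = edlib.align(target_region, expected, task="distance")["editDistance"]
        if d == ham:  # substitutions alone explain it; ties resolve to discard
            return "discard"
    aln = edlib.align(target_region, expected, mode="NW", task="path")
    cut = len(expected) - policy.cut_from_3p
    lo, hi = cut - policy.window, cut + policy.window
    pos = 0  # coordinate in expected
    saw_indel = False
    hit_window = False
    for n, op in _cigar_ops(aln["cigar"]):
        if op in ("=", "X", "M"):
            pos += n
        elif op == "I":  # extra bases in the read at boundary `pos`
            saw_indel = True
            if lo <= pos <= hi:
                hit_window = True
        elif op == "D":  # bases of `expected` missing from the read
            saw_indel = True
            if pos < hi and pos + n > lo:
                hit_window = True
            pos += n
    if saw_indel and hit_window:
        return "indel"
    return "discard"


def _cigar_ops(cigar: str):
    n = ""
    for ch in cigar:
        if ch.isdigit():
            n += ch
        else:
            yield int(n), ch
            n = ""


# --- rates ----------------------------------------------------------------


def compute_indel_rates(
    dayn_obs: pd.DataFrame,
    index: DesignIndex,
    whitelist: Optional[pd.DataFrame] = None,
    min_rbc: int = 20,
    policy: IndelPolicy = IndelPolicy(),
) -> pd.DataFrame:
    """Per-member indel rates from (optionally whitelisted) observations.

    Returns one record per design member (members never observed appear as
    dropouts with ``n_reads = 0`` and an absent rate). ``excluded`` flags
    members supported by fewer than ``min_rbc`` distinct whitelisted rBCs;
    their rate is still reported. ``indel_rate = n_indel / (n_reads -
    n_discarded)``.
    """
    obs = dayn_obs[dayn_obs["anchors_ok"] & dayn_obs["member_id"].notna()].copy()
    n_nonwhite = 0
    if whitelist is not None:
        before = len(obs)
        key = set(zip(whitelist["member_id"].astype(int), whitelist["rbc"]))
        mask = [
            (int(m), r) in key for m, r in zip(obs["member_id"], obs["rbc"])
        ]
        obs = obs[mask]
        n_nonwhite = before - len(obs)

    calls = [
        call_indel(row.target_obs, index.expected_region(int(row.member_id)), policy)
        for row in obs.itertuples(index=False)
    ]
    obs["call"] = calls
    records = []
    grouped = dict(tuple(obs.groupby(obs["member_id"].astype(int))))
    for member in index.design["member_id"].astype(int):
        grp = grouped.get(member)
        if grp is None:
            records.append(
                {
                    "member_id": member, "n_rbc": 0, "n_reads": 0, "n_indel_reads": 0,
                    "n_intact": 0, "n_discarded": 0, "indel_rate": np.nan, "excluded": True,
                }
            )
            continue
        n_reads = len(grp)
        n_indel = int((grp["call"] == "indel").sum())
        n_intact = int((grp["call"] == "intact").sum())
        n_disc = int((grp["call"] == "discard").sum())
        denom = n_reads - n_disc
        records.append(
            {
                "member_id": member,
                "n_rbc": int(grp["rbc"].nunique()),
                "n_reads": n_reads,
                "n_indel_reads": n_indel,
                "n_intact": n_intact,
                "n_discarded": n_disc,
                "indel_rate": n_indel / denom if denom > 0 else np.nan,
                "excluded": grp["rbc"].nunique() < min_rbc,
            }
        )
    out = pd.DataFrame(records)
    out.attrs["n_non_whitelisted_reads"] = n_nonwhite
    return out


def off_on_ratios(
    records: pd.DataFrame,
    design: pd.DataFrame,
    min_on_target: float = 0.02,
) -> pd.DataFrame:
    """Normalise each member's rate by its group's matched member of equal length.

    The ratio is computed only for (group, length) strata whose matched
    member has an indel rate above ``min_on_target`` (groups below it carry
    no usable signal); matched members themselves get ratio 1. Strata whose
    matched member is missing or rate-less get an absent ratio.
    """
    cols = ["member_id", "group_id", "spacer_length", "category"]
    df = records.merge(design[cols], on="member_id", how="left")
    matched = df[df["category"] == "matched"]
    on_rate = {
        (int(r.group_id), int(r.spacer_length)): r.indel_rate
        for r in matched.itertuples(index=False)
    }
    ratios = []
    for r in df.itertuples(index=False):
        key = (int(r.group_id), int(r.spacer_length))
        on = on_rate.get(key, np.nan)
        if not np.isfinite(on) or on <= min_on_target or not np.isfinite(r.indel_rate):
            ratios.append(np.nan)
        elif r.category == "matched":
            ratios.append(1.0)
        else:
            ratios.append(r.indel_rate / on)
    df["off_on_ratio"] = ratios
    return df


# --- aggregations ---------------------------------------------------------


def _derived_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Attach the stratification keys used by the summary views."""
    from .model import featurize

    df = df.copy()
    df["length"] = df["spacer_length"].astype(int)
    positions = df["positions"].fillna("").astype(str)
    pos_lists = [
        tuple(int(p) for p in s.split(",") if p != "") for s in positions
    ]
    df["position"] = [p[0] if len(p) == 1 else np.nan for p in pos_lists]
    df["position_pair"] = [
        f"{p[0]},{p[1]}" if len(p) == 2 else None for p in pos_lists
    ]
    mm_type = []
    for r in df.itertuples(index=False):
        if r.category == "single_mismatch":
            d = featurize(r.spacer, r.target)[0]
            mm_type.append(f"{d.rna_base}:{d.dna_base}")
        else:
            mm_type.append(None)
    df["mismatch_type"] = mm_type
    return df


def aggregate_tolerance(
    records: pd.DataFrame,
    design: pd.DataFrame,
    by: Sequence[str] = ("position", "length"),
) -> pd.DataFrame:
    """Mean off:on ratio with 95% CI per stratum.

    ``by`` may combine: position, length, mismatch_type, category,
    position_pair. Rows lacking any requested key (e.g. a double mismatch
    has no single ``position``) or lacking a ratio are left out; empty
    strata are simply absent. The returned counts therefore sum to the
    number of contributing members.
    """
    valid_keys = {"position", "length", "mismatch_type", "category", "position_pair"}
    by = list(by)
    unknown = set(by) - valid_keys
    if unknown:
        raise ValueError(f"unknown aggregation keys: {sorted(unknown)}")
    need = ["spacer", "target", "positions", "category", "spacer_length"]
    add = [c for c in need if c not in records.columns]
    df = records.merge(design[["member_id"] + add], on="member_id") if add else records.copy()
    df = _derived_columns(df)
    df = df[df["off_on_ratio"].notna()]
    for key in by:
        df = df[df[key].notna()]
    if df.empty:
        return pd.DataFrame(columns=by + ["mean_ratio", "ci95_lo", "ci95_hi", "n"])
    rows = []
    for keys, grp in df.groupby(by, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        vals = grp["off_on_ratio"].to_numpy()
        mean = float(vals.mean())
        if len(vals) > 1:
            half = float(1.96 * vals.std(ddof=1) / np.sqrt(len(vals)))
        else:
            half = np.nan
        rows.append(dict(zip(by, keys), mean_ratio=mean, ci95_lo=mean - half, ci95_hi=mean + half, n=len(vals)))
    return pd.DataFrame(rows)


def replicate_concordance(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    thresholds: Iterable[int] = (1, 2, 5, 10, 15, 20, 25, 30),
) -> pd.DataFrame:
    """Pearson R^2 between replicate indel rates as the rBC floor rises.

    For each minimum-rBC threshold, members passing the floor in both
    replicates (with finite rates) contribute; the retained fraction is
    relative to the full design. Fewer than 3 shared members gives an
    absent R^2.
    """
    merged = records_a.merge(records_b, on="member_id", suffixes=("_a", "_b"))
    n_total = len(merged)
    rows = []
    for t in thresholds:
        sel = (
            (merged["n_rbc_a"] >= t)
            & (merged["n_rbc_b"] >= t)
            & merged["indel_rate_a"].notna()
            & merged["indel_rate_b"].notna()
        )
        sub = merged[sel]
        if len(sub) >= 3 and sub["indel_rate_a"].nunique() > 1:
            r = stats.pearsonr(sub["indel_rate_a"], sub["indel_rate_b"]).statistic
            r2 = float(r * r)
        else:
            r2 = np.nan
        rows.append(
            {
                "min_rbc": t,
                "r_squared": r2,
                "n_members": int(len(sub)),
                "retained_fraction": len(sub) / n_total if n_total else np.nan,
            }
        )
    return pd.DataFrame(rows)
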