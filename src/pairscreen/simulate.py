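"""Synthetic pairwise-screen data generator with recorded ground truth.

Emulates the data-generating process of a pooled guide-target screen:
library cassettes carry oligo-synthesis errors (per-base substitutions and
occasional single indels); each lentiviral integration is tagged with a
random 8-nt rBC; after nuclease delivery each integration is edited with
probability ``g_j * prod f(pos,type)`` given by a known ground-truth
penalty model, placing an indel at the cut site; paired-end reads (read 1
covering spacer + rBC, read 2 covering target + PAM + Hamming barcode) are
emitted with configurable sequencing error. Every random draw derives from
a single seed, so identical configurations produce byte-identical FASTQ,
and the truth log is sufficient to compute every downstream pipeline
output exactly.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .design import PAM, CassetteLayout
from .dna import BASES, random_seq, revcomp
from .model import MISMATCH_TYPES, PenaltyMatrix, featurize

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_truth",
    "expected_rate",
    "simulate_integrations",
    "simulate_reads",
    "write_truth_log",
    "read_truth_log",
]

# stream labels for per-stage child seeds
_STAGE_TRUTH, _STAGE_INTEGRATION, _STAGE_READS = 1, 2, 3


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated screen.

    Defaults emulate the regime of an array-synthesised pooled library
    sequenced on a paired-end 2x150 run: ~2% per-base synthesis
    substitution over the variable region (which leaves roughly a quarter
    of ~60-nt variable regions error-free), a 10% per-oligo chance of one
    synthesis indel, ~30 independent integrations per member, 5 reads per
    rBC, and a 0.1% per-base sequencing error.
    """

    seed: int = 0
    synthesis_error_rate: float = 0.02  # per-base substitution, variable region
    synthesis_indel_rate: float = 0.10  # per-oligo single indel probability
    integrations_per_member: float = 30.0
    integration_distribution: str = "poisson"  # "poisson" | "fixed"
    reads_per_rbc: float = 5.0
    reads_distribution: str = "fixed"  # "fixed" | "poisson"
    sequencing_error_rate: float = 0.001  # per base, substitutions only
    read_length: int = 150
    timepoints: tuple[int, ...] = (0, 3, 14)
    editing_saturation: Mapping[int, float] = field(
        default_factory=lambda: {3: 1.0, 14: 1.0}
    )
    unique_rbc: str = "global"  # "global" | "member"

    def __post_init__(self):
        for r in (self.synthesis_error_rate, self.synthesis_indel_rate, self.sequencing_error_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.integration_distribution not in ("poisson", "fixed"):
            raise ValueError("integration_distribution must be poisson or fixed")
        if self.reads_distribution not in ("fixed", "poisson"):
            raise ValueError("reads_distribution must be fixed or poisson")

    def saturation(self, day: int) -> float:
        if day == 0:
            return 0.0
        return float(self.editing_saturation.get(day, 1.0))


@dataclass
class GroundTruth:
    """Known guide activities and mismatch/bulge penalties behind a simulation."""

    guide_activity: dict  # (group_id, spacer_length) -> g in [0, 1]
    penalty: dict  # spacer_length -> PenaltyMatrix
    bulge_penalty: dict  # {"proximal": factor, "distal": factor}

    def to_json(self, path) -> None:
        blob = {
            "guide_activity": [
                {"group_id": g, "spacer_length": L, "g": v}
                for (g, L), v in sorted(self.guide_activity.items())
            ],
            "penalty": {str(L): pm.f.tolist() for L, pm in self.penalty.items()},
            "bulge_penalty": self.bulge_penalty,
        }
        with open(path, "w") as fh:
            json.dump(blob, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            blob = json.load(fh)
        return cls(
            guide_activity={
                (e["group_id"], e["spacer_length"]): e["g"] for e in blob["guide_activity"]
            },
            penalty={int(L): PenaltyMatrix(int(L), np.array(f)) for L, f in blob["penalty"].items()},
            bulge_penalty=blob["bulge_penalty"],
        )


def simulate_truth(
    design: pd.DataFrame,
    config: SimConfig,
    g_beta: tuple[float, float] = (2.0, 2.0),
    bulge_penalty: Optional[dict] = None,
) -> GroundTruth:
    """Draw ground-truth parameters for a design, deterministically from the seed.

    Guide activities come from a Beta distribution (default Beta(2,2),
    spanning weak to strong guides); additive penalties ddG are iid
    Exponential with mean 1 and ``f = exp(-ddG)``, i.e. exactly the prior
    the inference model assumes. Bulges default to near-complete
    intolerance at PAM-proximal positions 1-18 and near-complete tolerance
    PAM-distally, mirroring heteroduplex geometry.
    """
    if design.empty:
        raise ValueError("design is empty")
    rng = np.random.default_rng([config.seed, _STAGE_TRUTH])
    guides = sorted(
        set(zip(design["group_id"].astype(int), design["spacer_length"].astype(int)))
    )
    g = {key: float(rng.beta(*g_beta)) for key in guides}
    lengths = sorted(design["spacer_length"].astype(int).unique())
    penalty = {}
    for L in lengths:
        ddg = rng.exponential(1.0, size=(L, len(MISMATCH_TYPES)))
        penalty[L] = PenaltyMatrix(L, np.exp(-ddg))
    return GroundTruth(g, penalty, bulge_penalty or {"proximal": 0.05, "distal": 0.9})


def expected_rate(row, truth: GroundTruth) -> float:
    """Forward-model editing probability for one design row (saturation 1)."""
    g = truth.guide_activity[(int(row["group_id"]), int(row["spacer_length"]))]
    cat = row["category"]
    if cat == "matched":
        return g
    if cat in ("single_mismatch", "double_mismatch", "double_transversion"):
        pm = truth.penalty[int(row["spacer_length"])]
        out = g
        for d in featurize(row["spacer"], row["target"]):
            out *= pm.value(d.position, d.type_index)
        return out
    if cat in ("insertion", "deletion"):
        out = g
        positions = [int(p) for p in str(row["positions"]).split(",") if p != ""]
        for p in positions:
            out *= truth.bulge_penalty["proximal" if p <= 18 else "distal"]
        return out
    if cat == "scrambled":
        return 0.0
    raise ValueError(f"unknown category {cat!r}")


# --- integrations ---------------------------------------------------------


def _variable_spans(layout: CassetteLayout, spacer_len: int, target_len: int):
    """(start, end) spans of spacer, target and Hamming barcode in the cassette."""
    s0 = len(layout.prefix)
    t0 = s0 + spacer_len + len(layout.scaffold5) + layout.rbc_length + len(layout.scaffold3)
    b0 = t0 + target_len + len(layout.pam) + len(layout.post_pam)
    return (s0, s0 + spacer_len), (t0, t0 + target_len), (b0, b0 + 15)


def simulate_integrations(
    design: pd.DataFrame,
    config: SimConfig,
    layout: CassetteLayout = CassetteLayout(),
) -> pd.DataFrame:
    """Draw lentiviral integrations with synthesis errors; return the truth log.

    One row per integration: the realised cassette sequence (rBC filled in,
    synthesis errors applied to the synthesised variable region: spacer,
    target and Hamming barcode; the rBC comes from a separate oligo), the
    cut-site coordinate within that cassette, and whether the cassette is
    error-free. rBC collisions (within a member, or globally when
    ``unique_rbc='global'``, the default) are redrawn and counted.
    """
    rng = np.random.default_rng([config.seed, _STAGE_INTEGRATION])
    rows = []
    seen_global: set[str] = set()
    redraws = 0
    for rec in design.itertuples(index=False):
        spans = _variable_spans(layout, len(rec.spacer), len(rec.target))
        cut_base = spans[1][1] - layout.cut_offset  # boundary coordinate of the blunt cut
        if config.integration_distribution == "poisson":
            n_int = int(rng.poisson(config.integrations_per_member))
        else:
            n_int = int(round(config.integrations_per_member))
        seen_member: set[str] = set()
        for _ in range(n_int):
            while True:
                rbc = random_seq(rng, layout.rbc_length)
                clash = rbc in seen_member or (
                    config.unique_rbc == "global" and rbc in seen_global
                )
                if not clash:
                    break
                redraws += 1
            seen_member.add(rbc)
            seen_global.add(rbc)
            cassette = layout.cassette(rec.spacer, rec.target, rec.barcode, rbc)
            seq = list(cassette)
            n_subs = 0
            for start, end in spans:
                for i in range(start, end):
                    if rng.random() < config.synthesis_error_rate:
                        seq[i] = rng.choice([b for b in BASES if b != seq[i]])
                        n_subs += 1
            cassette = "".join(seq)
            cut = cut_base
            has_indel = rng.random() < config.synthesis_indel_rate
            if has_indel:
                span = spans[int(rng.integers(0, 3))]
                pos = int(rng.integers(span[0], span[1]))
                size = int(rng.integers(1, 3))
                if rng.random() < 0.5:
                    cassette = cassette[:pos] + cassette[pos + size :]
                    if pos < cut:
                        cut -= min(size, cut - pos)
                else:
                    cassette = cassette[:pos] + random_seq(rng, size) + cassette[pos:]
                    if pos < cut:
                        cut += size
            rows.append(
                {
                    "member_id": int(rec.member_id),
                    "rbc": rbc,
                    "cassette": cassette,
                    "cut_pos": cut,
                    "error_free": n_subs == 0 and not has_indel,
                    "n_synth_subs": n_subs,
                    "synth_indel": bool(has_indel),
                }
            )
    log = pd.DataFrame(
        rows,
        columns=[
            "member_id", "rbc", "cassette", "cut_pos",
            "error_free", "n_synth_subs", "synth_indel",
        ],
    )
    log.attrs["rbc_redraws"] = redraws
    return log


# --- reads ----------------------------------------------------------------


def _apply_cut_indel(cassette: str, cut: int, rng: np.random.Generator) -> str:
    """Cas9 repair outcome: deletion spanning the cut (geometric sizes) or a
    1-2 nt insertion at the cut."""
    if rng.random() < 0.3:
        ins = random_seq(rng, int(rng.integers(1, 3)))
        return cassette[:cut] + ins + cassette[cut:]
    size = min(int(rng.geometric(0.4)), 10)
    start = max(0, cut - (size + 1) // 2)
    return cassette[:start] + cassette[start + size :]


def _seq_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in BASES if b != out[i]])
    return "".join(out)


def simulate_reads(
    truth_log: pd.DataFrame,
    truth: GroundTruth,
    design: pd.DataFrame,
    day: int,
    config: SimConfig,
    out_r1,
    out_r2,
) -> dict:
    """Write paired gzipped FASTQ for one timepoint; return per-day accounting.

    Each integration is edited with probability ``expected_rate * saturation(day)``
    (zero on Day 0); the edit is a cassette-level event, so every read of an
    edited integration carries the same cut-site indel. Read 1 is the first
    ``read_length`` bases of the cassette (spacer + rBC side), read 2 the
    reverse complement of the last ``read_length`` bases (barcode + target
    side). Gzip members are written with a zeroed timestamp, so identical
    configurations give byte-identical files.
    """
    if day not in config.timepoints:
        raise ValueError(f"day {day} not among configured timepoints {config.timepoints}")
    if config.read_length < 60:
        raise ValueError("read length too short to span the cassette anchors")
    rng = np.random.default_rng([config.seed, _STAGE_READS, day])
    sat = config.saturation(day)
    p_edit = {
        int(r.member_id): expected_rate(r._asdict(), truth) * sat
        for r in design.itertuples(index=False)
    }
    n_reads = n_edited = 0
    # zero mtime and no embedded filename: output depends only on content
    with gzip.GzipFile(
        filename="", fileobj=open(out_r1, "wb"), mode="wb", mtime=0
    ) as f1, gzip.GzipFile(
        filename="", fileobj=open(out_r2, "wb"), mode="wb", mtime=0
    ) as f2:
        for idx, rec in enumerate(truth_log.itertuples(index=False)):
            edited = sat > 0 and rng.random() < p_edit[int(rec.member_id)]
            cassette = (
                _apply_cut_indel(rec.cassette, int(rec.cut_pos), rng) if edited else rec.cassette
            )
            n_edited += int(edited)
            if config.reads_distribution == "poisson":
                k = int(rng.poisson(config.reads_per_rbc))
            else:
                k = int(round(config.reads_per_rbc))
            for j in range(k):
                r1 = _seq_errors(cassette[: config.read_length], config.sequencing_error_rate, rng)
                r2 = _seq_errors(
                    revcomp(cassette)[: config.read_length], config.sequencing_error_rate, rng
                )
                name = f"sim:d{day}:i{idx}:r{j}:m{rec.member_id}:{rec.rbc}:{'E' if edited else 'U'}"
                qual1, qual2 = "I" * len(r1), "I" * len(r2)
                f1.write(f"@{name}/1\n{r1}\n+\n{qual1}\n".encode())
                f2.write(f"@{name}/2\n{r2}\n+\n{qual2}\n".encode())
                n_reads += 1
    return {"day": day, "n_integrations": len(truth_log), "n_edited": n_edited, "n_read_pairs": n_reads}


def write_truth_log(log: pd.DataFrame, path) -> None:
    log.to_csv(path, sep="\t", index=False)


def read_truth_log(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
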