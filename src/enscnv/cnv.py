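"""CNV call data model, I/O and rare/common classification.

A copy-number call is an interval on a chromosome with a state (loss,
gain, homozygous loss, or hemizygous loss on chrX), an inheritance mode
and a patient group.  Case calls are classified as *rare* against a
control CNV cohort: a call is common when the fraction of control
samples carrying a same-state-class change covering >= ``min_overlap``
of the call reaches the frequency cut-off (default 0.026%, chosen to
match the prevalence of Hirschsprung disease).

Coordinates are stored 0-based half-open (BED convention).  Tables
printed with 1-based inclusive coordinates are converted on input via
the ``onebased`` dialect.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Valid copy-number states.
STATES = frozenset({"loss", "gain", "homozygous_loss", "hemizygous_loss"})

#: States pooled as "loss-like" when matching similar-state control changes.
LOSS_LIKE = frozenset({"loss", "homozygous_loss", "hemizygous_loss"})

INHERITANCE = frozenset({"de_novo", "maternal", "paternal", "unknown"})

#: Default control-cohort frequency cut-off below which a CNV is rare.
DEFAULT_FREQ_CUTOFF = 0.00026


class CnvValidationError(ValueError):
    """Raised for malformed intervals or CNV call records."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) with 0-based coordinates."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise CnvValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def size(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class CnvCall:
    """One copy-number event in one sample."""

    sample_id: str
    interval: GenomicInterval
    state: str
    inheritance: str = "unknown"
    group: int = 4

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise CnvValidationError(f"unknown CNV state {self.state!r}")
        if self.inheritance not in INHERITANCE:
            raise CnvValidationError(f"unknown inheritance {self.inheritance!r}")
        if self.group not in (1, 2, 3, 4):
            raise CnvValidationError(f"group must be 1-4, got {self.group!r}")
        if self.state == "hemizygous_loss" and self.interval.chrom not in (
            "chrX",
            "X",
        ):
            raise CnvValidationError("hemizygous_loss is only valid on chrX")

    def state_class(self) -> str:
        """Matching class: loss-like states pool together, gains stand alone."""
        return "loss" if self.state in LOSS_LIKE else "gain"

    def is_loss_like(self) -> bool:
        return self.state in LOSS_LIKE


@dataclass(frozen=True)
class RarityCall:
    """A case call annotated with its control-cohort frequency."""

    call: CnvCall
    matched_controls: int
    control_n: int
    frequency: float
    is_rare: bool


# ---------------------------------------------------------------------------
# I/O


def read_cnv_table(path, coordinate_dialect: str = "bed0") -> list[CnvCall]:
    """Read a TSV of CNV calls.

    Required columns: sample, chrom, start, end, state.  Optional:
    inheritance, group.  ``coordinate_dialect`` is ``bed0`` (0-based
    half-open, stored as-is) or ``onebased`` (1-based inclusive, as in
    printed tables; converted to half-open by start-1).
    """
    if coordinate_dialect not in ("bed0", "onebased"):
        raise ValueError(f"unknown coordinate dialect {coordinate_dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    required = {"sample", "chrom", "start", "end", "state"}
    missing = required - set(df.columns)
    if missing:
        raise CnvValidationError(f"{path}: missing columns {sorted(missing)}")
    calls: list[CnvCall] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            start = int(row.start)
            end = int(row.end)
            if coordinate_dialect == "onebased":
                start -= 1
            calls.append(
                CnvCall(
                    sample_id=str(row.sample),
                    interval=GenomicInterval(str(row.chrom), start, end),
                    state=str(row.state),
                    inheritance=str(getattr(row, "inheritance", "unknown")),
                    group=int(getattr(row, "group", 4)),
                )
            )
        except (CnvValidationError, ValueError) as exc:
            raise CnvValidationError(f"{path}, line {idx}: {exc}") from exc
    return calls


def write_cnv_table(calls: Iterable[CnvCall], path, coordinate_dialect: str = "bed0") -> None:
    """Write calls as TSV; inverse of :func:`read_cnv_table`."""
    if coordinate_dialect not in ("bed0", "onebased"):
        raise ValueError(f"unknown coordinate dialect {coordinate_dialect!r}")
    rows = []
    for c in calls:
        start = c.interval.start + 1 if coordinate_dialect == "onebased" else c.interval.start
        rows.append(
            {
                "sample": c.sample_id,
                "chrom": c.interval.chrom,
                "start": start,
                "end": c.interval.end,
                "state": c.state,
                "inheritance": c.inheritance,
                "group": c.group,
            }
        )
    cols = ["sample", "chrom", "start", "end", "state", "inheritance", "group"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_cnv_bed(calls: Iterable[CnvCall], path) -> None:
    """Write calls as 4+-column BED with the state in the name field."""
    rows = [
        {
            "chrom": c.interval.chrom,
            "start": c.interval.start,
            "end": c.interval.end,
            "name": f"{c.sample_id}|{c.state}",
            "score": 0,
            "strand": ".",
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# Overlap and rarity classification


def overlap_fraction(
    query: GenomicInterval, covering: Sequence[GenomicInterval]
) -> float:
    """Fraction of ``query`` covered by the union of ``covering`` intervals.

    Intervals on other chromosomes are ignored; the union is taken so
    tiled control calls are not double-counted.
    """
    segs = sorted(
        (max(iv.start, query.start), min(iv.end, query.end))
        for iv in covering
        if iv.chrom == query.chrom and iv.start < query.end and iv.end > query.start
    )
    covered = 0
    cur_start, cur_end = None, None
    for s, e in segs:
        if cur_end is None:
            cur_start, cur_end = s, e
        elif s <= cur_end:
            cur_end = max(cur_end, e)
        else:
            covered += cur_end - cur_start
            cur_start, cur_end = s, e
    if cur_end is not None:
        covered += cur_end - cur_start
    return covered / query.size()


def _controls_by_sample(
    controls: Iterable[CnvCall],
) -> dict[tuple[str, str, str], list[GenomicInterval]]:
    index: dict[tuple[str, str, str], list[GenomicInterval]] = {}
    for c in controls:
        key = (c.sample_id, c.state_class(), c.interval.chrom)
        index.setdefault(key, []).append(c.interval)
    return index


def classify_rare(
    call: CnvCall,
    controls: Sequence[CnvCall],
    control_n: int,
    min_overlap: float = 0.75,
    freq_cutoff: float = DEFAULT_FREQ_CUTOFF,
    reciprocal: bool = False,
) -> RarityCall:
    """Classify one case call as rare vs common against a control cohort.

    A control sample *matches* when the union of its same-state-class
    calls on the call's chromosome covers >= ``min_overlap`` of the
    call.  With ``reciprocal=True`` at least one single control call
    must additionally be covered >= ``min_overlap`` by the case call.
    ``frequency`` = matched samples / ``control_n`` (cohort size, which
    may exceed the number of samples with calls); rare iff frequency <
    ``freq_cutoff``.  Use ``freq_cutoff <= 1/control_n`` for a strict
    "absent from controls" rule.
    """
    if control_n <= 0:
        raise ValueError("control_n must be positive")
    n_ctrl_samples = len({c.sample_id for c in controls})
    if control_n < n_ctrl_samples:
        raise ValueError(
            f"control_n={control_n} is smaller than the {n_ctrl_samples} "
            "distinct control samples supplied"
        )
    return _classify_indexed(
        call, _controls_by_sample(controls), control_n, min_overlap, freq_cutoff, reciprocal
    )


def _classify_indexed(
    call: CnvCall,
    index: dict[tuple[str, str, str], list[GenomicInterval]],
    control_n: int,
    min_overlap: float,
    freq_cutoff: float,
    reciprocal: bool,
) -> RarityCall:
    cls = call.state_class()
    chrom = call.interval.chrom
    matched = 0
    for (sample, state_cls, c_chrom), ivs in index.items():
        if state_cls != cls or c_chrom != chrom:
            continue
        if overlap_fraction(call.interval, ivs) < min_overlap:
            continue
        if reciprocal and not any(
            overlap_fraction(iv, [call.interval]) >= min_overlap for iv in ivs
        ):
            continue
        matched += 1
    freq = matched / control_n
    rare = freq < freq_cutoff
    log.debug(
        "%s %s:%d-%d %s matched=%d freq=%.3g rare=%s",
        call.sample_id, chrom, call.interval.start, call.interval.end,
        call.state, matched, freq, rare,
    )
    return RarityCall(call, matched, control_n, freq, rare)


def classify_cohort(
    calls: Sequence[CnvCall],
    controls: Sequence[CnvCall],
    control_n: int,
    min_overlap: float = 0.75,
    freq_cutoff: float = DEFAULT_FREQ_CUTOFF,
    reciprocal: bool = False,
    exclude_self: bool = False,
) -> list[RarityCall]:
    """Classify every call in a cohort against the control set.

    With ``exclude_self=True`` a call's own sample is removed from the
    control index before matching (leave-one-out, for classifying the
    control cohort against itself).
    """
    if control_n <= 0:
        raise ValueError("control_n must be positive")
    index = _controls_by_sample(controls)
    out = []
    for call in calls:
        idx = index
        if exclude_self:
            idx = {k: v for k, v in index.items() if k[0] != call.sample_id}
        out.append(
            _classify_indexed(call, idx, control_n, min_overlap, freq_cutoff, reciprocal)
        )
    return out


def size_zscores(
    calls: Sequence[RarityCall], stratify_by_state: bool = False
) -> pd.DataFrame:
    """Z-scores of rare-CNV sizes over the supplied reference set.

    z = (size - mean) / sd with the sample sd (ddof=1), over all rare
    calls; with ``stratify_by_state`` the reference set is computed
    within each state class (loss-like vs gain).
    """
    rare = [rc for rc in calls if rc.is_rare]
    if len(rare) < 2:
        raise ValueError("need >= 2 rare calls to compute size z-scores")
    df = pd.DataFrame(
        {
            "sample": [rc.call.sample_id for rc in rare],
            "group": [rc.call.group for rc in rare],
            "state": [rc.call.state for rc in rare],
            "state_class": [rc.call.state_class() for rc in rare],
            "size": [rc.call.interval.size() for rc in rare],
        }
    )

    def _z(sizes: pd.Series) -> pd.Series:
        sd = sizes.std(ddof=1)
        if not math.isfinite(sd) or sd == 0:
            raise ValueError("zero variance in CNV sizes; z-scores undefined")
        return (sizes - sizes.mean()) / sd

    if stratify_by_state:
        df["z"] = df.groupby("state_class", group_keys=False)["size"].apply(_z)
    else:
        df["z"] = _z(df["size"])
    return df
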