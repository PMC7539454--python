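"""Per-sample cytosine methylation state calls.

A methylome sample maps loci -- identified by (seqname, 1-based
position, strand, sequence context) -- to diploid epigenotype states
coded 0 (u/u), 0.5 (m/u) and 1 (m/m).  Input is a tab-separated file
with columns seqname, position, strand, context and status (U/I/M), or a
read-count table from which hard U/M states are called with a one-tailed
binomial test against the bisulphite non-conversion rate, corrected by
the Benjamini-Yekutieli procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CONTEXTS",
    "StateCounts",
    "MethylomeSample",
    "read_methylome",
    "write_methylome",
    "call_states_binomial",
    "read_regions",
    "filter_by_regions",
    "state_proportions",
]

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")
_STATUS_TO_STATE = {"U": 0.0, "I": 0.5, "M": 1.0}
_STATE_TO_STATUS = {0.0: "U", 0.5: "I", 1.0: "M"}
_INDEX_NAMES = ["seqname", "position", "strand", "context"]


@dataclass(frozen=True)
class StateCounts:
    """Counts of loci in states u/u (x1), m/u (x2), m/m (x3)."""

    x1: int
    x2: int
    x3: int

    @property
    def N(self) -> int:
        return self.x1 + self.x2 + self.x3


@dataclass
class MethylomeSample:
    """One individual's locus -> state map.

    ``states`` is a float Series indexed by (seqname, position, strand,
    context) with values in {0, 0.5, 1}.
    """

    sample_id: str
    states: pd.Series

    def __post_init__(self) -> None:
        s = self.states
        if not isinstance(s, pd.Series):
            raise TypeError("states must be a pandas Series")
        if s.index.nlevels != 4:
            raise ValueError("states index must have 4 levels " + str(_INDEX_NAMES))
        if len(s) and not s.index.is_unique:
            raise ValueError(f"duplicate loci in sample {self.sample_id!r}")
        if len(s):
            vals = np.asarray(s.to_numpy(), dtype=float)
            if not np.isin(vals, [0.0, 0.5, 1.0]).all():
                bad = sorted(set(vals) - {0.0, 0.5, 1.0})
                raise ValueError(f"states outside {{0, 0.5, 1}}: {bad[:5]}")
        self.states = s.astype(float)
        self.states.index.names = _INDEX_NAMES

    @property
    def n_loci(self) -> int:
        return len(self.states)

    def state_counts(self) -> StateCounts:
        v = self.states.to_numpy()
        return StateCounts(int((v == 0.0).sum()), int((v == 0.5).sum()), int((v == 1.0).sum()))

    def restrict_context(self, contexts: Iterable[str]) -> "MethylomeSample":
        keep = self.states.index.get_level_values("context").isin(set(contexts))
        return MethylomeSample(self.sample_id, self.states[keep])


def _make_index(df: pd.DataFrame) -> pd.MultiIndex:
    pos = pd.to_numeric(df["position"], errors="raise").astype(np.int64)
    if (pos < 1).any():
        raise ValueError("positions must be 1-based integers >= 1")
    bad_ctx = set(df["context"].unique()) - set(CONTEXTS)
    if bad_ctx:
        raise ValueError(f"unknown contexts {sorted(bad_ctx)}; expected {CONTEXTS}")
    bad_strand = set(df["strand"].unique()) - {"+", "-"}
    if bad_strand:
        raise ValueError(f"unknown strands {sorted(bad_strand)}")
    return pd.MultiIndex.from_arrays(
        [df["seqname"].astype(str), pos, df["strand"], df["context"]],
        names=_INDEX_NAMES,
    )


def read_methylome(
    path,
    context_filter: Optional[Iterable[str]] = None,
    sample_id: Optional[str] = None,
) -> MethylomeSample:
    """Read a methylome TSV (seqname, position, strand, context, status).

    Status tokens are U (unmethylated), I (intermediate/epiheterozygous)
    and M (methylated).  Gzip-compressed files are read transparently.
    Row order is irrelevant; duplicate loci are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"seqname", "position", "strand", "context", "status"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"methylome file {path} missing columns {sorted(missing)}")
    bad = set(df["status"].unique()) - set(_STATUS_TO_STATE)
    if bad:
        raise ValueError(f"unknown status tokens {sorted(bad)}; expected U/I/M")
    if context_filter is not None:
        df = df[df["context"].isin(set(context_filter))]
    states = pd.Series(
        df["status"].map(_STATUS_TO_STATE).to_numpy(dtype=float), index=_make_index(df)
    )
    if sample_id is None:
        name = str(path)
        sample_id = name.rsplit("/", 1)[-1].split(".")[0]
    return MethylomeSample(sample_id, states)


def write_methylome(sample: MethylomeSample, path) -> None:
    df = sample.states.index.to_frame(index=False)
    df["status"] = [_STATE_TO_STATUS[v] for v in sample.states.to_numpy()]
    df.to_csv(path, sep="\t", index=False)


def call_states_binomial(
    counts: Union[pd.DataFrame, str],
    error_rate: float,
    fdr: float = 0.05,
    sample_id: str = "sample",
) -> MethylomeSample:
    """Call hard U/M states from methylated/total read counts.

    Per locus, the upper-tail binomial p-value of observing at least
    ``meth_reads`` methylated reads out of ``total_reads`` under the
    error (non-conversion) rate is computed; Benjamini-Yekutieli
    adjusted p-values at or below ``fdr`` yield state 1, otherwise 0.
    No intermediate states are produced.  Loci with zero coverage are
    dropped with a log message.
    """
    if isinstance(counts, (str, bytes)) or hasattr(counts, "__fspath__"):
        counts = pd.read_csv(counts, sep="\t")
    required = {"seqname", "position", "strand", "context", "meth_reads", "total_reads"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"count table missing columns {sorted(missing)}")
    if not (0.0 < error_rate < 1.0):
        raise ValueError(f"error_rate={error_rate} must lie in (0, 1)")
    meth = counts["meth_reads"].to_numpy(dtype=np.int64)
    total = counts["total_reads"].to_numpy(dtype=np.int64)
    if (meth < 0).any() or (meth > total).any():
        raise ValueError("need 0 <= meth_reads <= total_reads")
    covered = total > 0
    if not covered.all():
        logger.warning("dropping %d loci with zero coverage", int((~covered).sum()))
        counts = counts[covered]
        meth, total = meth[covered], total[covered]
    # P(X >= meth | total, error_rate); sf(k-1) is the upper tail at k
    pvals = _stats.binom.sf(meth - 1, total, error_rate)
    reject, p_adj, _, _ = multipletests(pvals, alpha=fdr, method="fdr_by")
    states = pd.Series(
        np.where(p_adj <= fdr, 1.0, 0.0), index=_make_index(counts)
    )
    return MethylomeSample(sample_id, states)


def read_regions(path, fmt: Optional[str] = None) -> pd.DataFrame:
    """Read genomic regions from BED (0-based half-open) or GFF3
    (1-based closed) into a 1-based closed (seqname, start, end) frame."""
    name = str(path).lower()
    if fmt is None:
        if name.endswith((".bed", ".bed.gz")):
            fmt = "bed"
        elif name.endswith((".gff", ".gff3", ".gff.gz", ".gff3.gz")):
            fmt = "gff3"
        else:
            raise ValueError(f"cannot infer region file format from {path}")
    if fmt == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        df = df[~df[0].astype(str).str.startswith(("track", "browser"))]
        out = pd.DataFrame(
            {
                "seqname": df[0].astype(str),
                "start": df[1].astype(np.int64) + 1,  # to 1-based closed
                "end": df[2].astype(np.int64),
            }
        )
    elif fmt == "gff3":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        out = pd.DataFrame(
            {
                "seqname": df[0].astype(str),
                "start": df[3].astype(np.int64),
                "end": df[4].astype(np.int64),
            }
        )
    else:
        raise ValueError(f"unknown region file format {fmt!r}")
    return out[out["end"] >= out["start"]].reset_index(drop=True)


def _merged_intervals(group: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    iv = group.sort_values("start")[["start", "end"]].to_numpy()
    starts, ends = [], []
    for s, e in iv:
        if ends and s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts), np.asarray(ends)


def filter_by_regions(
    sample: MethylomeSample, regions: Union[pd.DataFrame, str]
) -> MethylomeSample:
    """Retain loci whose position falls within any region."""
    if not isinstance(regions, pd.DataFrame):
        regions = read_regions(regions)
    if len(regions) == 0 or sample.n_loci == 0:
        return MethylomeSample(sample.sample_id, sample.states.iloc[0:0])
    keep = np.zeros(sample.n_loci, dtype=bool)
    seqnames = sample.states.index.get_level_values("seqname").to_numpy()
    positions = sample.states.index.get_level_values("position").to_numpy()
    for seq, group in regions.groupby("seqname"):
        mask = seqnames == seq
        if not mask.any():
            continue
        starts, ends = _merged_intervals(group)
        pos = positions[mask]
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos <= ends[np.clip(idx, 0, None)])
        keep[mask] = inside
    return MethylomeSample(sample.sample_id, sample.states[keep])


def state_proportions(
    samples: Sequence[MethylomeSample],
) -> tuple[pd.DataFrame, float]:
    """Per-sample state counts and the pooled mean u/u proportion.

    Returns a frame indexed by sample id with columns x1, x2, x3, N and
    p1 (= x1/N), together with p_bar_1, the mean of p1 across samples.
    """
    if len(samples) == 0:
        raise ValueError("need at least one sample")
    rows = {}
    for s in samples:
        if s.n_loci == 0:
            raise ValueError(f"sample {s.sample_id!r} is empty")
        c = s.state_counts()
        rows[s.sample_id] = {"x1": c.x1, "x2": c.x2, "x3": c.x3, "N": c.N, "p1": c.x1 / c.N}
    df = pd.DataFrame.from_dict(rows, orient="index")
    return df, float(df["p1"].mean())
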