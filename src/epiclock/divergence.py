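"""Pairwise 5mC divergence and assembly of the model-ready dataset.

The mean absolute divergence between samples i and j is

    D_ij = (1/N) sum_k I(s_ik, s_jk),

where I is 0 for identical states, 1/2 when exactly one state is the
epiheterozygote (0.5) and 1 for opposite homozygotes -- i.e. exactly
|s_ik - s_jk| under the (0, 0.5, 1) coding.  N is the number of loci
measured in both samples; by default the locus intersection is taken per
pair (a ``common_loci`` switch restricts all pairs to the global common
set instead).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .methylome import MethylomeSample, state_proportions
from .pedigree import Pedigree

__all__ = [
    "indicator",
    "pair_divergence",
    "DivergenceDataset",
    "build_dataset",
]

PAIR_COLUMNS = ["sample_i", "sample_j", "t_i", "t_j", "t_ij", "delta_t", "D", "N_shared"]

_VALID_STATES = (0.0, 0.5, 1.0)


def indicator(s_a: float, s_b: float) -> float:
    """Divergence indicator I(s_a, s_b) = |s_a - s_b| on {0, 0.5, 1}."""
    if s_a not in _VALID_STATES or s_b not in _VALID_STATES:
        raise ValueError(f"states ({s_a}, {s_b}) outside {{0, 0.5, 1}}")
    return abs(s_a - s_b)


def pair_divergence(a: MethylomeSample, b: MethylomeSample) -> tuple[float, int]:
    """Mean absolute divergence over loci shared by both samples."""
    if a.states.index.equals(b.states.index):
        va, vb = a.states.to_numpy(), b.states.to_numpy()
    else:
        common = a.states.index.intersection(b.states.index)
        if len(common) == 0:
            raise ValueError(
                f"samples {a.sample_id!r} and {b.sample_id!r} share no loci"
            )
        va = a.states.reindex(common).to_numpy()
        vb = b.states.reindex(common).to_numpy()
    if len(va) == 0:
        raise ValueError(f"samples {a.sample_id!r} and {b.sample_id!r} share no loci")
    return float(np.mean(np.abs(va - vb))), int(len(va))


@dataclass
class DivergenceDataset:
    """All unique sample pairs with times and divergences, plus the
    founder-state proportions and the pooled mean u/u proportion.

    ``pairs`` has columns sample_i, sample_j, t_i, t_j, t_ij, delta_t,
    D, N_shared (times on the internal founder-at-1 scale).
    """

    pairs: pd.DataFrame
    p1_obs: float
    p3_obs: float
    p_bar_1: float

    def __post_init__(self) -> None:
        missing = set(PAIR_COLUMNS) - set(self.pairs.columns)
        if missing:
            raise ValueError(f"pairs frame missing columns {sorted(missing)}")
        for name in ("p1_obs", "p3_obs", "p_bar_1"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        d = self.pairs["D"].to_numpy(dtype=float)
        if np.any(d < -1e-12) or np.any(d > 1 + 1e-12):
            raise ValueError("divergences outside [0, 1]")
        self.pairs = self.pairs.reset_index(drop=True)

    @property
    def M(self) -> int:
        return len(self.pairs)

    def replace_divergence(self, d: np.ndarray) -> "DivergenceDataset":
        pairs = self.pairs.copy()
        pairs["D"] = np.asarray(d, dtype=float)
        return DivergenceDataset(pairs, self.p1_obs, self.p3_obs, self.p_bar_1)

    def to_tsv(self, path) -> None:
        header = (
            f"# p1_obs={self.p1_obs!r}\n# p3_obs={self.p3_obs!r}\n"
            f"# p_bar_1={self.p_bar_1!r}\n"
        )
        buf = io.StringIO()
        self.pairs[PAIR_COLUMNS].to_csv(buf, sep="\t", index=False)
        with open(path, "w") as fh:
            fh.write(header + buf.getvalue())

    @classmethod
    def from_tsv(cls, path) -> "DivergenceDataset":
        meta = {}
        with open(path) as fh:
            text = fh.read()
        for line in text.splitlines():
            if line.startswith("#") and "=" in line:
                key, val = line.lstrip("# ").split("=", 1)
                meta[key.strip()] = float(val)
        pairs = pd.read_csv(io.StringIO(text), sep="\t", comment="#")
        return cls(
            pairs,
            meta.get("p1_obs", 0.0),
            meta.get("p3_obs", 0.0),
            meta.get("p_bar_1", meta.get("p1_obs", 0.0)),
        )


def build_dataset(
    pedigree: Pedigree,
    samples: Sequence[MethylomeSample],
    founder_sample: Optional[str] = None,
    common_loci: bool = False,
) -> DivergenceDataset:
    """Assemble divergences and divergence times for all sample pairs.

    Every sample id must resolve to a pedigree node (via ``sample_ref``
    or node id).  Founder-state proportions (p1_obs, p3_obs) come from
    ``founder_sample`` when given, otherwise they are averaged over all
    samples; the pooled p_bar_1 is always the across-sample mean u/u
    proportion.
    """
    by_id = {}
    for s in samples:
        if s.sample_id in by_id:
            raise ValueError(f"duplicate sample id {s.sample_id!r}")
        by_id[s.sample_id] = s
    for sid in by_id:
        pedigree.resolve_sample(sid)  # raises if unattached

    if common_loci and len(samples) > 1:
        common = samples[0].states.index
        for s in samples[1:]:
            common = common.intersection(s.states.index)
        if len(common) == 0:
            raise ValueError("no loci shared by all samples")
        by_id = {
            sid: MethylomeSample(sid, s.states.reindex(common))
            for sid, s in by_id.items()
        }

    times = pedigree.pair_times(sorted(by_id))
    rows = []
    for pt in times:
        d, n = pair_divergence(by_id[pt.sample_i], by_id[pt.sample_j])
        rows.append(
            (pt.sample_i, pt.sample_j, pt.t_i, pt.t_j, pt.t_ij, pt.delta_t, d, n)
        )
    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS)

    props, p_bar_1 = state_proportions(list(by_id.values()))
    if founder_sample is not None:
        if founder_sample not in props.index:
            raise ValueError(f"founder sample {founder_sample!r} not among samples")
        row = props.loc[founder_sample]
        p1_obs = row["x1"] / row["N"]
        p3_obs = row["x3"] / row["N"]
    else:
        p1_obs = float((props["x1"] / props["N"]).mean())
        p3_obs = float((props["x3"] / props["N"]).mean())
    return DivergenceDataset(pairs, float(p1_obs), float(p3_obs), p_bar_1)
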