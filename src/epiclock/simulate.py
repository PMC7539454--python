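"""Forward simulation of diploid epigenotypes through a pedigree.

Loci are independent three-state Markov chains.  The founder draws its
states i.i.d. from a supplied distribution; every edge of the pedigree
then advances the chain with the per-time-unit kernel G' -- either one
multinomial draw per elapsed integer time unit (``step_mode="unit"``,
the literal generative process) or a single draw from G'^duration per
edge (``step_mode="edge"``, distributionally identical by the
Chapman-Kolmogorov equation and much faster; also the only mode that
accepts non-integer edge durations).  An observation layer flips each
emitted state to one of the two other states with a symmetric
misclassification probability, emulating the measurement error that the
divergence model's intercept c absorbs.

The simulator doubles as the brute-force Monte Carlo oracle for the
expected-divergence formula.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .kernels import (
    EpimutationParams,
    FounderDistribution,
    KernelPowers,
    ModelSpec,
    build_kernel,
    stationary_distribution,
)
from .methylome import MethylomeSample, write_methylome
from .pedigree import Pedigree

__all__ = [
    "SimulationConfig",
    "sample_founder",
    "evolve_pedigree",
    "oracle_expected_divergence",
    "equilibrium_founder",
    "write_simulated_dataset",
]

_STATE_OF_CODE = np.array([0.0, 0.5, 1.0])


@dataclass(frozen=True)
class SimulationConfig:
    """Generative settings.

    ``misclass_rate`` flips an observed state to one of the two other
    states uniformly; ``dropout_rate`` drops each locus from each
    sample's observation independently, mimicking per-sample sequencing
    coverage gaps (real pairs share only the loci measured in both).
    """

    spec: ModelSpec
    params: EpimutationParams
    n_loci: int
    founder_pi: FounderDistribution
    misclass_rate: float = 0.0
    seed: int = 0
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_loci < 0:
            raise ValueError("n_loci must be >= 0")
        if not (0.0 <= self.misclass_rate < 1.0):
            raise ValueError("misclass_rate must lie in [0, 1)")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")


def equilibrium_founder(spec: ModelSpec, params: EpimutationParams) -> FounderDistribution:
    """Stationary distribution of the model kernel, as a founder state."""
    g = build_kernel(spec, params).g_norm
    return FounderDistribution(stationary_distribution(g))


def sample_founder(
    n_loci: int, founder_pi: FounderDistribution, seed_or_rng=0
) -> np.ndarray:
    """i.i.d. founder state codes (0, 1, 2 for u/u, m/u, m/m)."""
    rng = np.random.default_rng(seed_or_rng)
    return _categorical(rng, np.tile(founder_pi.pi, (n_loci, 1)))


def _categorical(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """One categorical draw per row of a (n, 3) probability matrix."""
    u = rng.random(len(probs))
    c1 = probs[:, 0]
    c2 = c1 + probs[:, 1]
    return ((u >= c1).astype(np.int8) + (u >= c2).astype(np.int8))


def _advance(
    rng: np.random.Generator,
    states: np.ndarray,
    kp: KernelPowers,
    duration: float,
    step_mode: str,
) -> np.ndarray:
    if duration == 0:
        return states.copy()
    if step_mode == "unit":
        if abs(duration - round(duration)) > 1e-9:
            raise ValueError(
                f"non-integer edge duration {duration}; use step_mode='edge' "
                "for fractional stepping"
            )
        g = kp.g
        out = states
        for _ in range(int(round(duration))):
            out = _categorical(rng, g[out])
        return out
    if step_mode == "edge":
        t = np.clip(kp.power(duration), 0.0, None)
        t = t / t.sum(axis=1, keepdims=True)
        return _categorical(rng, t[states])
    raise ValueError(f"unknown step_mode {step_mode!r}")


def _observe(rng: np.random.Generator, states: np.ndarray, e: float) -> np.ndarray:
    obs = states.copy()
    if e > 0:
        flip = rng.random(len(states)) < e
        shift = rng.integers(1, 3, size=int(flip.sum()), dtype=np.int8)
        obs[flip] = (obs[flip] + shift) % 3
    return obs


def _loci_index(n_loci: int) -> pd.MultiIndex:
    return pd.MultiIndex.from_arrays(
        [
            np.repeat("chr1", n_loci),
            np.arange(1, n_loci + 1, dtype=np.int64),
            np.repeat("+", n_loci),
            np.repeat("CG", n_loci),
        ],
        names=["seqname", "position", "strand", "context"],
    )


def evolve_pedigree(
    pedigree: Pedigree,
    config: SimulationConfig,
    step_mode: str = "unit",
) -> dict[str, MethylomeSample]:
    """Simulate methylomes for every sampled node of the pedigree.

    True states propagate along edges; the observation (misclassification)
    layer applies only to the emitted samples, so a sampled progenitor
    passes its uncorrupted states on to its descendants.  Returns a map
    sample_id -> MethylomeSample (falling back to node ids for sampled
    nodes without a ``sample_ref``).  Fully deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    kp = KernelPowers(build_kernel(config.spec, config.params).g_norm)
    index = _loci_index(config.n_loci)

    true_states: dict[str, np.ndarray] = {
        pedigree.root: sample_founder(config.n_loci, config.founder_pi, rng)
    }
    out: dict[str, MethylomeSample] = {}

    import networkx as nx

    order = list(nx.topological_sort(pedigree.graph))
    for nid in order:
        if nid not in true_states:
            parent = pedigree.ancestor_chain(nid)[1]
            duration = pedigree.node(nid).time - pedigree.node(parent).time
            true_states[nid] = _advance(rng, true_states[parent], kp, duration, step_mode)
        node = pedigree.node(nid)
        if node.is_sample or (node.sample_ref is None and pedigree.graph.out_degree(nid) == 0):
            sid = node.sample_ref if node.sample_ref is not None else nid
            obs = _observe(rng, true_states[nid], config.misclass_rate)
            states = pd.Series(_STATE_OF_CODE[obs], index=index)
            if config.dropout_rate > 0.0:
                keep = rng.random(config.n_loci) >= config.dropout_rate
                states = states[keep]
            out[sid] = MethylomeSample(sid, states)
    return out


def oracle_expected_divergence(
    spec: ModelSpec,
    params: EpimutationParams,
    times,
    founder_pi: FounderDistribution,
    reps: int,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte Carlo estimate of the expected divergence, with its SE.

    Simulates ``reps`` independent loci: the ancestor state is drawn
    from pi G'^(t_ij - 1), the two descendants from the matching rows of
    G'^(t_i - t_ij) and G'^(t_j - t_ij), and the divergence indicator is
    averaged.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if hasattr(times, "t_i"):
        t_i, t_j, t_ij = float(times.t_i), float(times.t_j), float(times.t_ij)
    else:
        t_i, t_j, t_ij = map(float, times)
    if t_ij < 1.0 - 1e-9 or t_i < t_ij - 1e-9 or t_j < t_ij - 1e-9:
        raise ValueError("invalid pair times")
    rng = np.random.default_rng(seed)
    kp = KernelPowers(build_kernel(spec, params).g_norm)
    anc_dist = founder_pi.pi @ kp.power(t_ij - 1.0)
    anc_dist = np.clip(anc_dist, 0, None)
    anc_dist /= anc_dist.sum()
    anc = _categorical(rng, np.tile(anc_dist, (reps, 1)))
    a = np.clip(kp.power(t_i - t_ij), 0, None)
    b = np.clip(kp.power(t_j - t_ij), 0, None)
    a /= a.sum(axis=1, keepdims=True)
    b /= b.sum(axis=1, keepdims=True)
    si = _categorical(rng, a[anc])
    sj = _categorical(rng, b[anc])
    ind = np.abs(_STATE_OF_CODE[si] - _STATE_OF_CODE[sj])
    est = float(ind.mean())
    se = float(ind.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
    return est, se


def write_simulated_dataset(
    pedigree: Pedigree,
    config: SimulationConfig,
    outdir,
    step_mode: str = "unit",
) -> dict:
    """Emit per-sample methylome TSVs, pedigree tables and a truth JSON
    in the exact dialects the loaders read.  Returns the truth record."""
    import os

    os.makedirs(outdir, exist_ok=True)
    samples = evolve_pedigree(pedigree, config, step_mode=step_mode)
    for sid, sample in samples.items():
        write_methylome(sample, os.path.join(outdir, f"{sid}.methylome.tsv"))
    nodes = pd.DataFrame(
        [
            (n.node_id, n.time, n.sample_ref if n.sample_ref is not None else "")
            for n in pedigree.nodes.values()
        ],
        columns=["node_id", "time", "sample_ref"],
    )
    edges = pd.DataFrame(list(pedigree.graph.edges), columns=["parent_id", "child_id"])
    nodes.to_csv(os.path.join(outdir, "nodes.tsv"), sep="\t", index=False)
    edges.to_csv(os.path.join(outdir, "edges.tsv"), sep="\t", index=False)
    truth = {
        "system": config.spec.system,
        "form": config.spec.form,
        "alpha": config.params.alpha,
        "beta": config.params.beta,
        "w": config.params.w,
        "gamma": config.params.gamma,
        "founder_pi": list(map(float, config.founder_pi.pi)),
        "misclass_rate": config.misclass_rate,
        "n_loci": config.n_loci,
        "seed": config.seed,
    }
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2)
    return truth
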