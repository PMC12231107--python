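"""Synthetic inputs with planted ground truth.

Every input the pipeline consumes can be generated here with a known
planted signal recorded in a machine-readable truth dictionary, so all
downstream stages are testable without any external data:

* replicate OD600 growth screens with planted sensitive/resistant strains,
* percent-growth score tables for hit-calling simulations,
* confidence-scored interactomes (random, scale-free, or planted-partition),
* GMT gene-set collections with planted over-representation,
* per-cell GFP/RFP fluorescence tables with planted abundance and
  localization shifts.

All generators are pure functions of their parameters and a master seed;
per-entity substreams (see :mod:`chemnet._rng`) keep draws stable when
entities are added.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream

COMPARTMENTS = (
    "cytosol", "nucleus", "vacuole", "ER",
    "plasma_membrane", "endosome", "cytoplasmic_foci", "other",
)


# ---------------------------------------------------------------------------
# Truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenTruth:
    """Planted ground truth for a growth screen.

    ``multipliers`` maps a planted strain id to a positive effect
    multiplier: values in (0, 1) mark sensitive strains, values > 1
    resistant strains.  Unlisted strains are neutral (multiplier 1).
    """

    strains: tuple[str, ...]
    multipliers: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.05
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.strains:
            raise ValueError("strain list is empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        unknown = set(self.multipliers) - set(self.strains)
        if unknown:
            raise ValueError(f"planted ids not among strains: {sorted(unknown)}")
        for s, m in self.multipliers.items():
            if not m > 0:
                raise ValueError(f"multiplier for {s} must be > 0, got {m}")

    @property
    def sensitive(self) -> set[str]:
        return {s for s, m in self.multipliers.items() if m < 1}

    @property
    def resistant(self) -> set[str]:
        return {s for s, m in self.multipliers.items() if m > 1}

    def multiplier(self, strain: str) -> float:
        return float(self.multipliers.get(strain, 1.0))

    def as_dict(self) -> dict:
        return {
            "strains": list(self.strains),
            "multipliers": dict(self.multipliers),
            "planted_sensitive": sorted(self.sensitive),
            "planted_resistant": sorted(self.resistant),
            "noise_sd": self.noise_sd,
            "replicates": self.replicates,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class NetworkTruth:
    """Planted block structure and edge-confidence model for an interactome."""

    blocks: Mapping[str, int]          # node id -> block label
    p_in: float = 0.3
    p_out: float = 0.02
    frac_high_confidence: float = 0.5  # fraction of edges scored >= 900
    frac_experimental: float = 0.8     # fraction of edges with experimental evidence
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError("need 0 <= p_out < p_in <= 1")
        for f in (self.frac_high_confidence, self.frac_experimental):
            if not 0 <= f <= 1:
                raise ValueError("edge-score fractions must lie in [0, 1]")

    def as_dict(self) -> dict:
        return {
            "blocks": dict(self.blocks),
            "p_in": self.p_in,
            "p_out": self.p_out,
            "frac_high_confidence": self.frac_high_confidence,
            "frac_experimental": self.frac_experimental,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class GeneSetTruth:
    """Planted over-representation structure for a GMT collection."""

    universe_size: int = 2000
    n_sets: int = 100
    set_size: int = 10
    n_planted: int = 3
    planted_fraction: float = 0.8  # fraction of each planted set drawn from the query
    seed: int = 0

    def __post_init__(self) -> None:
        if self.set_size > self.universe_size:
            raise ValueError("set size exceeds universe")
        if self.n_planted > self.n_sets:
            raise ValueError("more planted sets than sets")
        if not 0 <= self.planted_fraction <= 1:
            raise ValueError("planted_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Growth screens
# ---------------------------------------------------------------------------

def logistic_od(t: np.ndarray | float, r: float, carrying_k: float,
                od0: float) -> np.ndarray | float:
    """Closed-form logistic growth curve OD(t) = K·od0·e^{rt} / (K + od0(e^{rt}−1))."""
    e = np.exp(r * np.asarray(t, dtype=float))
    return carrying_k * od0 * e / (carrying_k + od0 * (e - 1.0))


def gen_growth_screen(truth: ScreenTruth, times: Sequence[float],
                      r: float = 0.5, carrying_k: float = 2.0,
                      od0: float = 0.05) -> pd.DataFrame:
    """Simulate an OD600 liquid growth screen.

    Returns a long table (strain, condition, replicate, time_h, od600)
    with conditions ``vehicle`` and ``treated``.  Vehicle curves follow
    the control logistic model; under treatment a planted strain's growth
    rate ``r`` is scaled by its effect multiplier.  Noise is
    multiplicative log-normal on OD with relative s.d. ``truth.noise_sd``.
    """
    times = np.asarray(list(times), dtype=float)
    if times.size == 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be non-empty and strictly increasing")
    if min(r, carrying_k, od0) <= 0:
        raise ValueError("logistic parameters r, K, od0 must be positive")

    rows = []
    for strain in truth.strains:
        mult = truth.multiplier(strain)
        for condition, rate in (("vehicle", r), ("treated", r * mult)):
            clean = logistic_od(times, rate, carrying_k, od0)
            for rep in range(1, truth.replicates + 1):
                rng = substream(truth.seed, "growth", strain, condition, rep)
                if truth.noise_sd > 0:
                    od = clean * np.exp(rng.normal(0.0, truth.noise_sd, size=times.size))
                else:
                    od = clean.copy()
                rows.append(pd.DataFrame({
                    "strain": strain, "condition": condition, "replicate": rep,
                    "time_h": times, "od600": od,
                }))
    return pd.concat(rows, ignore_index=True)


def gen_screen_scores(truth: ScreenTruth, n_screens: int = 3) -> pd.DataFrame:
    """Simulate per-strain percent-growth scores across independent screens.

    A strain's true score is 100 × its effect multiplier (100 = neutral);
    each replicate observation is the true score under multiplicative
    log-normal noise.  Returns columns strain, screen, replicate, score.
    """
    if n_screens < 1:
        raise ValueError("n_screens must be >= 1")
    rows = []
    for strain in truth.strains:
        true_score = 100.0 * truth.multiplier(strain)
        for screen in range(1, n_screens + 1):
            rng = substream(truth.seed, "scores", strain, screen)
            noise = rng.normal(0.0, truth.noise_sd, size=truth.replicates)
            scores = true_score * np.exp(noise)
            for rep, sc in enumerate(scores, start=1):
                rows.append((strain, screen, rep, sc))
    return pd.DataFrame(rows, columns=["strain", "screen", "replicate", "score"])


# ---------------------------------------------------------------------------
# Interactomes
# ---------------------------------------------------------------------------

def _score_edges(edges: list[tuple[str, str]], rng: np.random.Generator,
                 frac_high: float, frac_exp: float) -> pd.DataFrame:
    """Attach STRING-like integer confidence scores to an edge list."""
    n = len(edges)
    high = rng.random(n) < frac_high
    combined = np.where(
        high,
        rng.integers(900, 1001, size=n),
        rng.integers(150, 900, size=n),
    )
    has_exp = rng.random(n) < frac_exp
    experimental = np.where(has_exp, rng.integers(150, 1001, size=n), 0)
    return pd.DataFrame({
        "protein1": [a for a, _ in edges],
        "protein2": [b for _, b in edges],
        "experimental": experimental.astype(int),
        "combined_score": combined.astype(int),
    })


def planted_partition_truth(n_blocks: int, block_size: int, p_in: float = 0.3,
                            p_out: float = 0.02, seed: int = 0,
                            **kwargs) -> NetworkTruth:
    """Convenience constructor: nodes g0000.. assigned to equal blocks."""
    blocks = {}
    for b in range(n_blocks):
        for i in range(block_size):
            blocks[f"g{b * block_size + i:04d}"] = b
    return NetworkTruth(blocks=blocks, p_in=p_in, p_out=p_out, seed=seed, **kwargs)


def gen_interactome(n_nodes: int, model: str = "erdos_renyi", *,
                    truth: NetworkTruth | None = None,
                    edge_p: float = 0.05, m_attach: int = 2,
                    frac_high_confidence: float = 0.5,
                    frac_experimental: float = 0.8,
                    seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Generate a STRING-like weighted edge table.

    model: ``erdos_renyi`` (edge probability ``edge_p``),
    ``preferential_attachment`` (Barabási–Albert, ``m_attach`` edges per
    new node), or ``planted_partition`` (block structure from ``truth``).
    Returns (edge table, truth dict).  Undirected, simple; each edge
    carries an integer combined_score in [150, 1000] and an
    experimental-channel score (0 when the edge has no experimental
    support).
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    rng = substream(seed, "interactome", model)

    if model == "planted_partition":
        if truth is None:
            raise ValueError("planted_partition requires a NetworkTruth")
        nodes = sorted(truth.blocks)
        edges = []
        for i, u in enumerate(nodes):
            for v in nodes[i + 1:]:
                p = truth.p_in if truth.blocks[u] == truth.blocks[v] else truth.p_out
                if rng.random() < p:
                    edges.append((u, v))
        truth_dict = truth.as_dict()
        frac_high_confidence = truth.frac_high_confidence
        frac_experimental = truth.frac_experimental
    elif model == "erdos_renyi":
        nodes = [f"g{i:04d}" for i in range(n_nodes)]
        edges = []
        for i, u in enumerate(nodes):
            for v in nodes[i + 1:]:
                if rng.random() < edge_p:
                    edges.append((u, v))
        truth_dict = {"model": model, "edge_p": edge_p, "seed": seed}
    elif model == "preferential_attachment":
        nodes = [f"g{i:04d}" for i in range(n_nodes)]
        # Barabási–Albert: each new node attaches to m distinct targets
        # chosen proportionally to current degree.
        targets = list(range(min(m_attach, n_nodes - 1)))
        repeated: list[int] = list(targets)
        edges = []
        for new in range(len(targets), n_nodes):
            chosen: set[int] = set()
            while len(chosen) < min(m_attach, new):
                pick = repeated[rng.integers(0, len(repeated))]
                chosen.add(pick)
            for t in chosen:
                edges.append((nodes[t], nodes[new]))
                repeated.extend([t, new])
        edges = [(min(a, b), max(a, b)) for a, b in edges]
        truth_dict = {"model": model, "m_attach": m_attach, "seed": seed}
    else:
        raise ValueError(f"unknown interactome model: {model!r}")

    edges = sorted(set(edges))
    table = _score_edges(edges, substream(seed, "edge_scores", model), frac_high_confidence,
                         frac_experimental)
    return table, truth_dict


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

def gen_genesets(truth: GeneSetTruth, query: Sequence[str] | None = None,
                 ) -> tuple[dict[str, set[str]], list[str], list[str], dict]:
    """Generate a gene-set collection with planted over-representation.

    Returns (collection, universe, query, truth dict).  Planted sets draw
    ``planted_fraction`` of their members from the query; decoy sets are
    uniform samples from the universe.  If ``query`` is None a random
    query of 20 genes is drawn from the universe.
    """
    universe = [f"y{i:05d}" for i in range(truth.universe_size)]
    rng = substream(truth.seed, "genesets")
    if query is None:
        query = sorted(rng.choice(universe, size=min(20, truth.universe_size),
                                  replace=False))
    query = list(query)
    if not set(query) <= set(universe):
        raise ValueError("query must be a subset of the universe")

    collection: dict[str, set[str]] = {}
    planted_names = []
    non_query = sorted(set(universe) - set(query))
    for i in range(truth.n_sets):
        name = f"set{i:03d}"
        srng = substream(truth.seed, "genesets", name)
        if i < truth.n_planted:
            n_from_query = min(round(truth.planted_fraction * truth.set_size),
                               len(query), truth.set_size)
            members = set(srng.choice(query, size=n_from_query, replace=False))
            pad = truth.set_size - len(members)
            if pad > 0:
                members |= set(srng.choice(non_query, size=pad, replace=False))
            planted_names.append(name)
        else:
            members = set(srng.choice(universe, size=truth.set_size, replace=False))
        collection[name] = members

    truth_dict = {
        "planted_enriched": planted_names,
        "universe_size": truth.universe_size,
        "set_size": truth.set_size,
        "planted_fraction": truth.planted_fraction,
        "query": list(query),
        "seed": truth.seed,
    }
    return collection, universe, query, truth_dict


# ---------------------------------------------------------------------------
# Per-cell microscopy tables
# ---------------------------------------------------------------------------

def gen_microscopy_table(n_strains: int = 30, n_cells: int = 200, *,
                         abundance_shifts: Mapping[str, float] | None = None,
                         localization_shifts: Mapping[str, tuple[str, str]] | None = None,
                         noise_sd: float = 0.1, seed: int = 0,
                         baseline_compartment: str = "cytosol",
                         ) -> tuple[pd.DataFrame, dict]:
    """Simulate per-cell GFP/RFP quantification for control and treated cells.

    ``abundance_shifts`` maps strain ids to planted percent changes of
    the treated GFP mean (e.g. +50 → ×1.5); ``localization_shifts`` maps
    strain ids to (control compartment, treated compartment).  Intensities
    are log-normal around strain means; the RFP reference channel is
    unshifted.  Returns (table, truth dict).
    """
    if n_cells < 10:
        raise ValueError("n_cells must be >= 10")
    abundance_shifts = dict(abundance_shifts or {})
    localization_shifts = dict(localization_shifts or {})
    for s, pct in abundance_shifts.items():
        if pct <= -100:
            raise ValueError(f"abundance shift for {s} must exceed -100%")
    for s, (a, b) in localization_shifts.items():
        for comp in (a, b):
            if comp not in COMPARTMENTS:
                raise ValueError(f"unknown compartment {comp!r}")

    strains = [f"s{i:03d}" for i in range(n_strains)]
    unknown = (set(abundance_shifts) | set(localization_shifts)) - set(strains)
    if unknown:
        raise ValueError(f"planted ids not among strains: {sorted(unknown)}")

    rows = []
    for strain in strains:
        gfp_mu, rfp_mu = 1000.0, 800.0
        for condition in ("control", "treated"):
            rng = substream(seed, "microscopy", strain, condition)
            scale = 1.0
            if condition == "treated" and strain in abundance_shifts:
                scale = 1.0 + abundance_shifts[strain] / 100.0
            gfp = gfp_mu * scale * np.exp(rng.normal(0, noise_sd, n_cells))
            rfp = rfp_mu * np.exp(rng.normal(0, noise_sd, n_cells))
            # 90% of cells in the condition's dominant compartment, the
            # remainder spread uniformly over the others.
            dominant = baseline_compartment
            if strain in localization_shifts:
                ctrl_comp, treat_comp = localization_shifts[strain]
                dominant = treat_comp if condition == "treated" else ctrl_comp
            others = [c for c in COMPARTMENTS if c != dominant]
            probs = [0.9 if c == dominant else 0.1 / len(others) for c in COMPARTMENTS]
            comps = rng.choice(COMPARTMENTS, size=n_cells, p=probs)
            rows.append(pd.DataFrame({
                "strain": strain, "condition": condition,
                "cell_id": np.arange(1, n_cells + 1),
                "gfp": gfp, "rfp": rfp, "compartment": comps,
            }))

    truth_dict = {
        "abundance_shifts": abundance_shifts,
        "localization_shifts": {s: list(v) for s, v in localization_shifts.items()},
        "noise_sd": noise_sd,
        "n_cells": n_cells,
        "seed": seed,
    }
    return pd.concat(rows, ignore_index=True), truth_dict
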