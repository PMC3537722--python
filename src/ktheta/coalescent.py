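"""Two-population coalescent machinery.

Time is measured in pairwise-coalescent units: one unit is Ne generations
for a uniparental genome, so the expected coalescence time of a pair of
lineages sampled within one population is exactly 1 unit, and the 4x-rule
calibration makes the population divergence time tau equal to K/theta.

The module provides

* a genealogy simulator for two populations that split tau units ago
  (within-population coalescence only before the split, free coalescence in
  the ancestral population after it),
* the probability of reciprocal monophyly for given (tau, n1, n2), estimated
  by Monte Carlo — the package's replacement for the unpublished
  sample-size/ratio table the method was originally used with, and
* a synthetic two-species alignment generator (infinite-sites by default)
  for end-to-end testing of the delimitation pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np

from .seqio import Alignment

__all__ = [
    "TwoSpeciesModel",
    "GNode",
    "Genealogy",
    "SimulationTruth",
    "simulate_genealogy",
    "reciprocal_monophyly",
    "prm_estimate",
    "PrmEstimate",
    "tau_from_ratio",
    "simulate_two_species_alignment",
    "prm_table",
]


@dataclass(frozen=True)
class TwoSpeciesModel:
    """A clean two-population split.

    tau: divergence time in pairwise-coalescent units; n1, n2: sample sizes;
    theta_site: 2*Ne*mu per site (the expected within-population pairwise
    difference); L: sites; mutation_model: "infinite_sites" or "jc".
    """

    tau: float
    n1: int
    n2: int
    theta_site: float = 0.01
    L: int = 1000
    mutation_model: str = "infinite_sites"

    def __post_init__(self) -> None:
        if self.tau < 0.0:
            raise ValueError("tau must be nonnegative")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("sample sizes must be >= 1")
        if self.theta_site < 0.0:
            raise ValueError("theta_site must be nonnegative")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.mutation_model not in ("infinite_sites", "jc"):
            raise ValueError("mutation_model must be 'infinite_sites' or 'jc'")


class GNode:
    """A genealogy node: tips carry a species tag, internals a merge time."""

    __slots__ = ("time", "species", "children", "label")

    def __init__(self, time: float = 0.0, species: int | None = None,
                 children: tuple = (), label: str | None = None):
        self.time = time
        self.species = species
        self.children = children
        self.label = label

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Genealogy:
    """A labelled binary gene tree over n1 + n2 tips with coalescent times."""

    root: GNode
    n1: int
    n2: int
    tips: list = field(default_factory=list)

    def postorder(self) -> Iterator[GNode]:
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done or node.is_leaf():
                yield node
            else:
                stack.append((node, True))
                stack.extend((c, False) for c in node.children)

    @property
    def tmrca(self) -> float:
        return self.root.time


def _pick_pair(k: int, rng: np.random.Generator) -> tuple[int, int]:
    i = int(rng.integers(k))
    j = int(rng.integers(k - 1))
    if j >= i:
        j += 1
    return (i, j) if i < j else (j, i)


def simulate_genealogy(model: TwoSpeciesModel, rng: np.random.Generator | int | None = None) -> Genealogy:
    """Simulate one gene genealogy under the two-population split model.

    Before tau, each population's lineage pairs coalesce at rate 1 per pair
    per unit; at tau the surviving lineages enter the ancestral population
    and coalesce freely at the same pairwise rate.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    tips1 = [GNode(species=1, label=f"sp1_{i:02d}") for i in range(model.n1)]
    tips2 = [GNode(species=2, label=f"sp2_{i:02d}") for i in range(model.n2)]
    pools = [list(tips1), list(tips2)]
    t = 0.0
    while True:
        k1, k2 = len(pools[0]), len(pools[1])
        rate1 = k1 * (k1 - 1) / 2.0
        rate2 = k2 * (k2 - 1) / 2.0
        rate = rate1 + rate2
        if rate == 0.0:
            break
        dt = rng.exponential(1.0 / rate)
        if t + dt >= model.tau:
            break
        t += dt
        pool = pools[0] if rng.random() < rate1 / rate else pools[1]
        i, j = _pick_pair(len(pool), rng)
        parent = GNode(time=t, children=(pool[i], pool[j]))
        pool[i] = parent
        del pool[j]
    t = model.tau
    pool = pools[0] + pools[1]
    while len(pool) > 1:
        k = len(pool)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = _pick_pair(k, rng)
        parent = GNode(time=t, children=(pool[i], pool[j]))
        pool[i] = parent
        del pool[j]
    return Genealogy(root=pool[0], n1=model.n1, n2=model.n2, tips=tips1 + tips2)


def reciprocal_monophyly(g: Genealogy) -> bool:
    """True iff each species' tips form a clade (singletons count as clades)."""
    target1 = (g.n1, 0)
    target2 = (0, g.n2)
    found1 = g.n1 == 1
    found2 = g.n2 == 1
    counts: dict[int, tuple[int, int]] = {}
    for node in g.postorder():
        if node.is_leaf():
            c = (1, 0) if node.species == 1 else (0, 1)
        else:
            c1 = c2 = 0
            for child in node.children:
                a, b = counts[id(child)]
                c1 += a
                c2 += b
            c = (c1, c2)
        counts[id(node)] = c
        if c == target1:
            found1 = True
        elif c == target2:
            found2 = True
    return found1 and found2


class PrmEstimate(NamedTuple):
    """Monte-Carlo estimate of P(reciprocal monophyly) with binomial SE."""

    p_hat: float
    se: float
    reps: int


def prm_estimate(tau: float, n1: int, n2: int, reps: int = 100_000, seed=None) -> PrmEstimate:
    """Probability that samples of n1 and n2 from populations that split tau
    units ago are reciprocally monophyletic in their gene genealogy.

    Estimated as the fraction of simulated genealogies that are reciprocally
    monophyletic; deterministic given *seed*.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    model = TwoSpeciesModel(tau=tau, n1=n1, n2=n2, theta_site=0.0, L=1)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        if reciprocal_monophyly(simulate_genealogy(model, rng)):
            hits += 1
    p = hits / reps
    return PrmEstimate(p_hat=p, se=math.sqrt(p * (1.0 - p) / reps), reps=reps)


def tau_from_ratio(ratio: float, mode: str = "birky") -> float:
    """Map an observed K/theta ratio to a divergence time in coalescent units.

    ``"birky"``: tau = ratio (the 4x-rule calibration, where K = 8*Ne*mu at
    T = 4*Ne generations and theta = 2*Ne*mu give K/theta = tau exactly).
    ``"ancestral_adjusted"``: tau = max(ratio - 1, 0), subtracting the
    expected ancestral-polymorphism contribution (E[K] = theta * (tau + 1)
    under the unconditioned coalescent).
    """
    if ratio < 0.0:
        raise ValueError("ratio must be nonnegative")
    if mode == "birky":
        return ratio
    if mode == "ancestral_adjusted":
        return max(ratio - 1.0, 0.0)
    raise ValueError(f"unknown tau mode {mode!r}")


@dataclass(frozen=True)
class SimulationTruth:
    """Sidecar record for a simulated alignment: the generating parameters."""

    tau: float
    theta_site: float
    L: int
    species: dict
    n_mutations: int
    genealogy: Genealogy


def simulate_two_species_alignment(
    model: TwoSpeciesModel, seed=None
) -> tuple[Alignment, SimulationTruth]:
    """Simulate a genealogy and drop mutations on it to produce an alignment.

    Mutations fall on branches as a Poisson process at rate theta_site/2 per
    site per unit, so the expected within-species pairwise difference equals
    theta_site and the expected between-species difference is
    theta_site * (tau + 1).  Infinite-sites placement (every mutation hits a
    fresh site) is the default; ``mutation_model="jc"`` allows multiple hits
    with Jukes-Cantor-style substitution.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = simulate_genealogy(model, rng)
    L = model.L
    rate = model.theta_site / 2.0

    # deterministic preorder walk; draw all mutation counts/sites/offsets first
    branches = []  # (child, length) in preorder
    stack = [g.root]
    while stack:
        node = stack.pop()
        for child in node.children:
            branches.append((child, node.time - child.time))
            stack.append(child)
    counts = [int(rng.poisson(rate * L * max(length, 0.0))) for _, length in branches]
    total = sum(counts)
    infinite = model.mutation_model == "infinite_sites"
    if infinite:
        if total > L:
            raise ValueError(
                f"{total} mutations exceed {L} sites under infinite-sites placement; "
                "increase L or use mutation_model='jc'"
            )
        site_pool = rng.permutation(L)[:total]
        cursor = 0
        sites = []
        for c in counts:
            sites.append(site_pool[cursor : cursor + c])
            cursor += c
    else:
        sites = [rng.integers(0, L, size=c) for c in counts]
    offsets = [rng.integers(1, 4, size=c) for c in counts]
    mut = {id(child): (s, o) for (child, _), s, o in zip(branches, sites, offsets)}

    ancestral = rng.integers(0, 4, size=L).astype(np.int8)
    seqs: dict[int, np.ndarray] = {}
    order = [(g.root, ancestral)]
    while order:
        node, seq = order.pop()
        for child in node.children:
            s, o = mut[id(child)]
            child_seq = seq
            if len(s):
                child_seq = seq.copy()
                child_seq[s] = (child_seq[s] + o) % 4
            if child.is_leaf():
                seqs[id(child)] = child_seq
            else:
                order.append((child, child_seq))

    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    records = []
    species = {}
    for tip in g.tips:
        row = alphabet[seqs[id(tip)]]
        records.append((tip.label, row.tobytes().decode("ascii")))
        species[tip.label] = tip.species
    aln = Alignment.from_sequences(records)
    truth = SimulationTruth(
        tau=model.tau,
        theta_site=model.theta_site,
        L=L,
        species=species,
        n_mutations=total,
        genealogy=g,
    )
    return aln, truth


def prm_table(taus, sample_pairs, reps: int = 10_000, seed=None):
    """P(reciprocal monophyly) grid over tau and (n1, n2) sample sizes.

    Returns a pandas DataFrame with columns tau, n1, n2, p_rm, se — the
    package's stand-in for the unpublished probability table the method's
    original users consulted.
    """
    import pandas as pd

    ss = np.random.SeedSequence(seed if seed is not None else 0)
    rows = []
    for tau in taus:
        for n1, n2 in sample_pairs:
            est = prm_estimate(tau, n1, n2, reps=reps, seed=ss.spawn(1)[0])
            rows.append({"tau": tau, "n1": n1, "n2": n2, "p_rm": est.p_hat, "se": est.se})
    return pd.DataFrame(rows)
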