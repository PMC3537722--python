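"""The K/theta estimators and decision rule.

Per clade: the mean pairwise uncorrected difference d-bar, nucleotide
diversity ``pi = d_bar * n/(n-1)``, and ``theta = pi / (1 - 4*pi/3)`` (an
estimate of 2*Ne*mu for a uniparental genome).  When a clade's sequences are
identical (d-bar = 0), pi is floored at ``2 / (L * n * (n-1))``, i.e. one
pairwise difference of 1/L among the n(n-1)/2 pairs.

Per pair of sister clades: the mean between-clade difference, uncorrected
(D) and corrected for multiple hits (K); the ratio of that divergence to the
larger of the two clade thetas; and the 4x rule — sister clades with
ratio >= 4 are inferred to be independently evolving species, otherwise they
are clades formed by drift within one species.  The probability of
reciprocal monophyly for the observed sample sizes is attached from the
two-population coalescent simulator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import coalescent
from .distances import DistanceMatrix, MODELS, count_site_patterns, distance_matrix
from .errors import AlignmentError, SaturationError
from .phylo import collapse_unsupported, leaf_set, mean_between
from .seqio import Alignment

__all__ = [
    "DiversityEstimate",
    "PairTest",
    "DelimitConfig",
    "DelimitationResult",
    "mean_pairwise_within",
    "pi_hat",
    "pi_floor_zero",
    "theta_hat",
    "between_clade_K",
    "ratio_test",
    "classify_pair",
    "diversity_estimate",
    "delimit",
    "pair_tests_frame",
]

logger = logging.getLogger(__name__)

DISTINCT = "distinct_species"
SINGLE = "single_species"
INDETERMINATE = "indeterminate"


# ---------------------------------------------------------------------------
# estimators


def mean_pairwise_within(aln: Alignment, clade: Iterable[str]) -> float | None:
    """Mean uncorrected pairwise difference within a clade.

    Returns ``None`` for a singleton clade (the caller decides how to handle
    it; theta must then come from the sister clade).
    """
    ids = list(clade)
    missing = [i for i in ids if i not in aln.ids]
    if missing:
        raise AlignmentError(f"clade members not in alignment: {missing}")
    if len(ids) < 2:
        return None
    codes = [aln.codes[aln.index(i)] for i in ids]
    total = 0.0
    npairs = 0
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            total += count_site_patterns(codes[a], codes[b]).p
            npairs += 1
    return total / npairs


def pi_hat(d_bar: float, n: int) -> float:
    """Nucleotide diversity: d-bar with the n/(n-1) sample-size correction."""
    if n < 2:
        raise ValueError("pi requires a clade of at least 2 sequences")
    if not 0.0 <= d_bar <= 1.0:
        raise ValueError("mean pairwise difference must lie in [0, 1]")
    return d_bar * n / (n - 1)


def pi_floor_zero(L: int, n: int) -> float:
    """Non-zero pi floor used when d-bar = 0: assume one pair differs at 1/L."""
    if n < 2:
        raise ValueError("pi floor requires a clade of at least 2 sequences")
    if L < 1:
        raise ValueError("alignment length must be positive")
    return 2.0 / (L * n * (n - 1))


def theta_hat(pi: float) -> float:
    """theta = 2*Ne*mu estimated as pi / (1 - 4*pi/3)."""
    if pi < 0.0:
        raise ValueError("pi must be nonnegative")
    if pi >= 0.75:
        raise ValueError("theta correction undefined for pi >= 3/4")
    return pi / (1.0 - 4.0 * pi / 3.0)


def between_clade_K(
    aln: Alignment,
    A: Iterable[str],
    B: Iterable[str],
    model: str = "jc69",
    allow_saturated: bool = False,
) -> tuple[float, float]:
    """Mean between-clade divergence: (D uncorrected, K corrected).

    D and K average over all cross pairs.  A saturated cross pair raises
    :class:`SaturationError` unless *allow_saturated* is set, in which case
    the pair is excluded from K (never from D) and a warning is logged.
    """
    A, B = list(A), list(B)
    if not A or not B:
        raise ValueError("both clades must be nonempty")
    if set(A) & set(B):
        raise ValueError("clades must be disjoint")
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    from .distances import correct_distance

    d_sum = 0.0
    k_sum = 0.0
    k_n = 0
    for a in A:
        ca = aln.codes[aln.index(a)]
        for b in B:
            counts = count_site_patterns(ca, aln.codes[aln.index(b)])
            d_sum += counts.p
            try:
                k_sum += correct_distance(counts, model)
                k_n += 1
            except SaturationError:
                if not allow_saturated:
                    raise SaturationError(
                        f"cross pair ({a!r}, {b!r}) is saturated under {model}"
                    ) from None
                logger.warning("excluding saturated pair (%s, %s) from K", a, b)
    D = d_sum / (len(A) * len(B))
    K = k_sum / k_n if k_n else float("inf")
    return D, K


def ratio_test(div: float, theta_a: float | None, theta_b: float | None) -> float:
    """Divergence-to-theta ratio using the larger (conservative) theta."""
    thetas = [t for t in (theta_a, theta_b) if t is not None]
    if not thetas or max(thetas) <= 0.0:
        raise ValueError(
            "both clade thetas are zero/absent; use the d=0 floor (pi_floor_zero) "
            "or estimate theta from the sister clade"
        )
    if div < 0.0:
        raise ValueError("divergence must be nonnegative")
    return div / max(thetas)


def classify_pair(ratio: float, ratio_threshold: float = 4.0) -> str:
    """The 4x rule: distinct species iff ratio >= threshold (inclusive)."""
    if ratio < 0.0:
        raise ValueError("ratio must be nonnegative")
    return DISTINCT if ratio >= ratio_threshold else SINGLE


# ---------------------------------------------------------------------------
# records


@dataclass(frozen=True)
class DiversityEstimate:
    """Per-clade diversity record: (n, d-bar, pi, theta)."""

    clade: str
    n: int
    L: int
    d_bar: float
    pi: float
    theta: float
    zero_d: bool = False


@dataclass(frozen=True)
class PairTest:
    """One tested pair of sister clades, mirroring the published table logic."""

    clade_a: str
    clade_b: str
    leaves_a: frozenset
    leaves_b: frozenset
    n1: int
    n2: int
    d_bar_a: float | None
    d_bar_b: float | None
    pi_a: float | None
    pi_b: float | None
    theta_a: float | None
    theta_b: float | None
    zero_d_a: bool
    zero_d_b: bool
    D: float
    K: float
    model: str
    divergence_used: str  # "D" or "K"
    theta_used: float | None
    ratio: float | None
    tau: float | None
    p_rm: float | None
    p_rm_se: float | None
    decision: str


def diversity_estimate(aln: Alignment, clade: Iterable[str], clade_id: str | None = None) -> DiversityEstimate:
    """DiversityEstimate for a clade, applying the d=0 floor when needed."""
    ids = list(clade)
    d_bar = mean_pairwise_within(aln, ids)
    if d_bar is None:
        raise ValueError("diversity_estimate requires n >= 2; singleton theta comes from the sister clade")
    zero_d = d_bar == 0.0
    pi = pi_floor_zero(aln.L, len(ids)) if zero_d else pi_hat(d_bar, len(ids))
    return DiversityEstimate(
        clade=clade_id or _clade_label(ids),
        n=len(ids),
        L=aln.L,
        d_bar=d_bar,
        pi=pi,
        theta=theta_hat(pi),
        zero_d=zero_d,
    )


def _clade_label(leaves: Iterable[str]) -> str:
    leaves = sorted(leaves)
    if len(leaves) == 1:
        return leaves[0]
    return f"{leaves[0]}+{len(leaves) - 1}"


# ---------------------------------------------------------------------------
# delimitation


@dataclass(frozen=True)
class DelimitConfig:
    """Tunable knobs of the delimitation traversal.

    ``d_switch`` picks which divergence feeds the ratio: D while D < switch
    (multiple hits negligible), else the model-corrected K.  ``tau_mode``
    maps the observed ratio to a divergence time for the P(RM) attachment:
    ``"birky"`` uses tau = ratio; ``"ancestral_adjusted"`` subtracts the
    expected ancestral-polymorphism contribution (tau = ratio - 1).
    Splits resting on an ad-hoc theta (the d=0 floor) and singleton splits
    against clades smaller than ``min_sister_for_singleton`` are demoted to
    "indeterminate" unless explicitly allowed.
    """

    model: str = "uncorrected"
    support_threshold: float = 70.0
    ratio_threshold: float = 4.0
    d_switch: float = 0.05
    prm_reps: int = 10_000
    seed: int | None = None
    tau_mode: str = "birky"
    min_sister_for_singleton: int = 5
    allow_floored_theta_split: bool = False


@dataclass
class DelimitationResult:
    """Outcome of :func:`delimit`: the species partition plus every pair test."""

    species: list[frozenset]
    assignments: dict[str, int]
    pair_tests: list[PairTest]
    config: DelimitConfig
    log: list[str] = field(default_factory=list)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def __iter__(self):
        yield self.assignments
        yield self.pair_tests


@dataclass
class _Cluster:
    leaves: frozenset
    frozen: bool = False


class _Delimiter:
    """Single-use state for one tips-first delimitation traversal."""

    def __init__(
        self,
        aln: Alignment,
        config: DelimitConfig,
        pmat: DistanceMatrix,
        kmat: DistanceMatrix | None,
        supports: Mapping[frozenset, float],
        universe: frozenset,
    ):
        self.aln = aln
        self.cfg = config
        self.pmat = pmat
        self.kmat = kmat
        self.supports = supports
        self.universe = universe
        self.pair_tests: list[PairTest] = []
        self.log: list[str] = []
        self._seed_seq = np.random.SeedSequence(
            config.seed if config.seed is not None else 0
        )

    def _is_supported_clade(self, leaves: frozenset) -> bool:
        """Is this cluster a bootstrap-demonstrated clade of the full tree?

        Singletons are not clades; a cluster whose complement holds fewer
        than two leaves induces only a trivial (unfalsifiable) split and
        counts as a clade; otherwise the bootstrap support of its bipartition
        must reach the collapse threshold.  Unions improvised by pooling
        inside a collapsed polytomy match no supported bipartition and are
        not themselves evidence of structure.
        """
        if len(leaves) < 2:
            return False
        if len(self.universe) - len(leaves) < 2:
            return True
        from .phylo import bipartition_key

        key = bipartition_key(leaves, self.universe)
        return self.supports.get(key, 0.0) >= self.cfg.support_threshold

    # -- statistics ------------------------------------------------------
    def _indices(self, leaves: frozenset) -> list[int]:
        return [self.pmat.index(l) for l in sorted(leaves)]

    def _within(self, leaves: frozenset) -> float | None:
        idx = self._indices(leaves)
        if len(idx) < 2:
            return None
        sub = self.pmat.values[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        return float(sub[iu].mean())

    def _cross(self, a: frozenset, b: frozenset) -> tuple[float, float]:
        ia, ib = self._indices(a), self._indices(b)
        D = float(self.pmat.values[np.ix_(ia, ib)].mean())
        if self.kmat is None:
            return D, D
        if np.any(self.kmat.saturated[np.ix_(ia, ib)]):
            raise SaturationError(
                f"saturated cross pair between {_clade_label(a)} and {_clade_label(b)}"
            )
        K = float(self.kmat.values[np.ix_(ia, ib)].mean())
        return D, K

    def _side_estimates(self, leaves: frozenset):
        """(d_bar, pi, theta, zero_d) for one side; Nones for a singleton."""
        n = len(leaves)
        if n < 2:
            return None, None, None, False
        d_bar = self._within(leaves)
        zero_d = d_bar == 0.0
        pi = pi_floor_zero(self.aln.L, n) if zero_d else pi_hat(d_bar, n)
        return d_bar, pi, theta_hat(pi), zero_d

    # -- pair testing ----------------------------------------------------
    def test_pair(self, x: _Cluster, y: _Cluster) -> _Cluster | tuple[_Cluster, _Cluster]:
        cfg = self.cfg
        a, b = x.leaves, y.leaves
        n1, n2 = len(a), len(b)
        d_a, pi_a, th_a, zd_a = self._side_estimates(a)
        d_b, pi_b, th_b, zd_b = self._side_estimates(b)
        D, K = self._cross(a, b)
        label_a, label_b = _clade_label(a), _clade_label(b)

        if n1 == 1 and n2 == 1:
            # two sister singletons: theta cannot be estimated for either side
            decision, ratio, theta_used, div_name, tau = INDETERMINATE, None, None, "D", None
            p_rm, p_se = 1.0, 0.0  # two singletons are trivially reciprocally monophyletic
        else:
            theta_used = max(t for t in (th_a, th_b) if t is not None)
            floored = (th_a == theta_used and zd_a) or (th_b == theta_used and zd_b)
            div_name = "D" if D < cfg.d_switch else "K"
            div = D if div_name == "D" else K
            ratio = ratio_test(div, th_a, th_b)
            decision = classify_pair(ratio, cfg.ratio_threshold)
            if decision == DISTINCT:
                if not (self._is_supported_clade(a) or self._is_supported_clade(b)):
                    # a species boundary needs at least one side demonstrated
                    # as a clade by the bootstrap, not improvised by pooling
                    decision = INDETERMINATE
                    self.log.append(
                        f"demoted split of ({label_a}, {label_b}): neither side is a "
                        "bootstrap-supported clade"
                    )
                elif floored and not cfg.allow_floored_theta_split:
                    decision = INDETERMINATE
                    self.log.append(
                        f"demoted split of ({label_a}, {label_b}): theta rests on the d=0 floor"
                    )
                elif (n1 == 1) != (n2 == 1) and max(n1, n2) < cfg.min_sister_for_singleton:
                    decision = INDETERMINATE
                    self.log.append(
                        f"demoted split of ({label_a}, {label_b}): singleton sister clade "
                        f"has fewer than {cfg.min_sister_for_singleton} members"
                    )
            tau = coalescent.tau_from_ratio(ratio, cfg.tau_mode)
            p_rm, p_se = self._prm(tau, n1, n2)

        self.pair_tests.append(
            PairTest(
                clade_a=label_a,
                clade_b=label_b,
                leaves_a=a,
                leaves_b=b,
                n1=n1,
                n2=n2,
                d_bar_a=d_a,
                d_bar_b=d_b,
                pi_a=pi_a,
                pi_b=pi_b,
                theta_a=th_a,
                theta_b=th_b,
                zero_d_a=zd_a,
                zero_d_b=zd_b,
                D=D,
                K=K,
                model=self.pmat.model if self.kmat is None else self.kmat.model,
                divergence_used=div_name,
                theta_used=theta_used,
                ratio=ratio,
                tau=tau,
                p_rm=p_rm,
                p_rm_se=p_se,
                decision=decision,
            )
        )
        if decision == DISTINCT:
            self.log.append(
                f"freeze: {label_a} vs {label_b} ratio {ratio:.2f} >= {cfg.ratio_threshold:g}"
            )
            return _Cluster(a, frozen=True), _Cluster(b, frozen=True)
        self.log.append(
            f"merge ({decision}): {label_a} + {label_b}"
            + (f" ratio {ratio:.2f}" if ratio is not None else "")
        )
        return _Cluster(a | b, frozen=x.frozen or y.frozen)

    def _prm(self, tau: float, n1: int, n2: int) -> tuple[float, float]:
        child = self._seed_seq.spawn(1)[0]
        est = coalescent.prm_estimate(tau, n1, n2, reps=self.cfg.prm_reps, seed=child)
        return est.p_hat, est.se

    # -- traversal -------------------------------------------------------
    def process(self, node: dendropy.Node) -> list[_Cluster]:
        kids = node.child_nodes()
        if not kids:
            return [_Cluster(frozenset({node.taxon.label}))]
        groups = [self.process(c) for c in kids]
        while len(groups) > 1:
            # fold together the two groups holding the closest cross-cluster pair
            best = None
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for ci, cx in enumerate(groups[gi]):
                        for cj, cy in enumerate(groups[gj]):
                            d = mean_between(self.pmat, cx.leaves, cy.leaves)
                            key = (d, min(cx.leaves), min(cy.leaves))
                            if best is None or key < best[0]:
                                best = (key, gi, gj, ci, cj)
            _, gi, gj, ci, cj = best
            cx, cy = groups[gi][ci], groups[gj][cj]
            outcome = self.test_pair(cx, cy)
            merged_group = [c for k, c in enumerate(groups[gi]) if k != ci]
            merged_group += [c for k, c in enumerate(groups[gj]) if k != cj]
            if isinstance(outcome, tuple):
                merged_group.extend(outcome)
            else:
                merged_group.append(outcome)
            groups = [g for k, g in enumerate(groups) if k not in (gi, gj)]
            groups.append(merged_group)
        return groups[0]


def delimit(
    aln: Alignment,
    tree: dendropy.Tree,
    supports: Mapping[frozenset, float],
    config: DelimitConfig | None = None,
    outgroup: Iterable[str] | None = None,
) -> DelimitationResult:
    """Tips-first species delimitation over a bootstrapped tree.

    Internal edges with support below the threshold are collapsed; sister
    clades are then tested from the tips toward the root.  A pair failing
    the ratio test is pooled into one putative species (n and d-bar
    recomputed on the union for all later tests); a pair passing it is
    frozen as two species.  Two sister singletons are indeterminate and are
    merged for upstream testing.  Every tested pair is recorded as a
    :class:`PairTest` with its P(reciprocal monophyly).

    *outgroup* leaves (if any) must form a child of the root (see
    :func:`ktheta.phylo.root_on_outgroup`); they are excluded from the
    partition.
    """
    cfg = config or DelimitConfig()
    tree_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    missing = tree_leaves - set(aln.ids)
    if missing:
        raise AlignmentError(f"tree leaves absent from alignment: {sorted(missing)}")

    pmat = distance_matrix(aln, "uncorrected")
    kmat = None
    if cfg.model != "uncorrected":
        kmat = distance_matrix(aln, cfg.model, on_saturation="flag")

    collapsed = collapse_unsupported(tree, supports, cfg.support_threshold)
    root = collapsed.seed_node
    og = frozenset(outgroup) if outgroup else frozenset()
    if og:
        ingroup_kids = [c for c in root.child_nodes() if leaf_set(c) != og]
        if len(ingroup_kids) == len(root.child_nodes()):
            raise AlignmentError("outgroup does not form a child of the root; root the tree first")
        if len(ingroup_kids) == 1:
            root = ingroup_kids[0]
        else:  # pragma: no cover - defensive; rooted trees have two root children
            raise AlignmentError("ambiguous ingroup after removing the outgroup")

    state = _Delimiter(aln, cfg, pmat, kmat, supports, tree_leaves)
    clusters = state.process(root)
    species = sorted((c.leaves for c in clusters), key=lambda s: min(s))
    assignments = {leaf: i + 1 for i, sp in enumerate(species) for leaf in sorted(sp)}
    state.log.append(f"final partition: {len(species)} species")
    return DelimitationResult(
        species=species,
        assignments=assignments,
        pair_tests=state.pair_tests,
        config=cfg,
        log=state.log,
    )


def pair_tests_frame(tests: Sequence[PairTest]) -> pd.DataFrame:
    """Tabular report of pair tests (pi/theta to 4 decimals, ratios to 1).

    Full precision is retained on the :class:`PairTest` records; rounding is
    applied only in this report, following the published table convention.
    """
    rows = []
    for t in tests:
        rows.append(
            {
                "clade_A": t.clade_a,
                "clade_B": t.clade_b,
                "n1": t.n1,
                "n2": t.n2,
                "d_bar_A": _r(t.d_bar_a, 4),
                "d_bar_B": _r(t.d_bar_b, 4),
                "pi_A": _r(t.pi_a, 4),
                "pi_B": _r(t.pi_b, 4),
                "theta_A": _r(t.theta_a, 4),
                "theta_B": _r(t.theta_b, 4),
                "D": _r(t.D, 4),
                "K": _r(t.K, 4),
                "model": t.model,
                "used": t.divergence_used,
                "theta_used": _r(t.theta_used, 4),
                "ratio": _r(t.ratio, 1),
                "P_RM": _r(t.p_rm, 4),
                "decision": t.decision,
            }
        )
    return pd.DataFrame(rows)


def _r(x: float | None, nd: int):
    return None if x is None else round(x, nd)
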