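"""Scikit-learn style estimator wrapping the full delimitation pipeline."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .core import DelimitConfig, delimit, pair_tests_frame
from .distances import distance_matrix
from .errors import ConfigError
from .phylo import bootstrap_supports, neighbor_joining, root_on_outgroup
from .seqio import Alignment, read_alignment

__all__ = ["KThetaDelimiter"]


class KThetaDelimiter(BaseEstimator):
    """Species delimitation with the K/theta ratio, as a clustering estimator.

    ``fit`` takes an :class:`~ktheta.seqio.Alignment` (or a FASTA path),
    builds a bootstrapped neighbor-joining tree, collapses weakly supported
    edges, and tests sister clades tips-first with the 4x rule, pooling
    clades that fail it.  Fitted attributes follow the scikit-learn
    convention (trailing underscore); ``labels_`` assigns a species index to
    every sequence (``-1`` marks outgroup sequences).

    Parameters
    ----------
    model:
        Distance correction for tree building and between-clade K:
        ``uncorrected`` (default), ``jc69``, ``k2p`` or ``k81``.
    bootstrap_replicates, support_threshold:
        Bootstrap sample count (default 1000) and the percent support an
        internal edge needs to survive (default 70).
    ratio_threshold:
        The 4x rule constant; sister clades at or above it are species.
    d_switch:
        Use the uncorrected divergence D while D < this value, the corrected
        K otherwise (default 0.05).
    prm_reps, tau_mode:
        Monte-Carlo replicates and ratio-to-tau mapping for the attached
        probability of reciprocal monophyly.
    min_sister_for_singleton, allow_floored_theta_split:
        Small-sample safeguards; see :class:`~ktheta.core.DelimitConfig`.
    outgroup:
        Leaf ids used to root the tree; excluded from the partition.
    seed:
        Required whenever any stochastic stage runs (bootstrap, P(RM)).
    """

    def __init__(
        self,
        model: str = "uncorrected",
        bootstrap_replicates: int = 1000,
        support_threshold: float = 70.0,
        ratio_threshold: float = 4.0,
        d_switch: float = 0.05,
        prm_reps: int = 10_000,
        tau_mode: str = "birky",
        min_sister_for_singleton: int = 5,
        allow_floored_theta_split: bool = False,
        outgroup: Sequence[str] | None = None,
        seed: int | None = None,
    ):
        self.model = model
        self.bootstrap_replicates = bootstrap_replicates
        self.support_threshold = support_threshold
        self.ratio_threshold = ratio_threshold
        self.d_switch = d_switch
        self.prm_reps = prm_reps
        self.tau_mode = tau_mode
        self.min_sister_for_singleton = min_sister_for_singleton
        self.allow_floored_theta_split = allow_floored_theta_split
        self.outgroup = outgroup
        self.seed = seed

    # ------------------------------------------------------------------
    def fit(self, X, y=None):
        """Run the pipeline on an alignment (or FASTA path)."""
        aln = X if isinstance(X, Alignment) else read_alignment(X)
        if self.seed is None:
            raise ConfigError("seed is required: bootstrap and P(RM) stages are stochastic")
        if self.bootstrap_replicates < 1:
            raise ConfigError("bootstrap_replicates must be >= 1")
        ss = np.random.SeedSequence(self.seed)
        boot_seed, prm_seed = ss.spawn(2)

        dm = distance_matrix(aln, self.model)
        tree = neighbor_joining(dm)
        supports = bootstrap_supports(
            aln, self.model, self.bootstrap_replicates, boot_seed, tree=tree
        )
        outgroup = tuple(self.outgroup) if self.outgroup else ()
        if outgroup:
            tree = root_on_outgroup(tree, outgroup)

        cfg = DelimitConfig(
            model=self.model,
            support_threshold=self.support_threshold,
            ratio_threshold=self.ratio_threshold,
            d_switch=self.d_switch,
            prm_reps=self.prm_reps,
            seed=int(prm_seed.generate_state(1)[0] % (2**31)),
            tau_mode=self.tau_mode,
            min_sister_for_singleton=self.min_sister_for_singleton,
            allow_floored_theta_split=self.allow_floored_theta_split,
        )
        result = delimit(aln, tree, supports, cfg, outgroup=outgroup or None)

        self.alignment_ = aln
        self.distance_matrix_ = dm
        self.tree_ = tree
        self.supports_ = supports
        self.result_ = result
        self.species_ = result.species
        self.assignments_ = result.assignments
        self.pair_tests_ = result.pair_tests
        self.n_species_ = result.n_species
        self.labels_ = np.array(
            [result.assignments.get(i, -1) for i in aln.ids], dtype=int
        )
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Fit and return the per-sequence species labels."""
        return self.fit(X).labels_

    def pair_report(self):
        """Pair-test table (pandas DataFrame) for the fitted alignment."""
        return pair_tests_frame(self.pair_tests_)
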