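"""Draw-level internal consistency of the modelled indicators.

All quantities are modelled independently, so nothing guarantees that the
14 method prevalences sum to the CPR or that the modern total stays below
it. This module enforces the nested-proportion structure on every draw:
method prevalences are raked (proportionally rescaled) to the CPR draw,
the modern methods are totalled into the mCPR, unmet need is the modelled
need share among non-users times (1 - CPR), and demand satisfied (SDG
3.7.1) is mCPR / (CPR + unmet need). Uncertainty intervals of derived
quantities are always computed from their own draw distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .methods import ALL_METHODS, DEFAULT_PRIORITY, MethodPriority

logger = logging.getLogger(__name__)


def rake_methods_to_cpr(method_draws: np.ndarray, cpr_draw) -> np.ndarray:
    """Scale the 14 method prevalences so they sum exactly to the CPR.

    ``method_draws`` has the method axis first: shape (14, ...) matching
    ``cpr_draw``'s shape. Cells where all methods are zero but CPR is
    positive get the CPR spread uniformly over the 14 methods (logged).
    """
    method_draws = np.asarray(method_draws, dtype=float)
    cpr = np.asarray(cpr_draw, dtype=float)
    if np.any((cpr < 0) | (cpr > 1)):
        raise ValueError("cpr draws outside [0,1]")
    total = method_draws.sum(axis=0)
    out = np.empty_like(method_draws)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(total > 0, cpr / np.where(total > 0, total, 1.0), 0.0)
    out = method_draws * scale
    degenerate = (total == 0) & (cpr > 0)
    if np.any(degenerate):
        logger.warning(
            "raking: %d cell-draws had zero method mass with positive CPR; "
            "spread uniformly", int(degenerate.sum())
        )
        out = np.where(degenerate, cpr / len(method_draws), out)
    return out


def compute_mcpr(raked: np.ndarray, priority: MethodPriority = DEFAULT_PRIORITY) -> np.ndarray:
    """Total the raked modern-method prevalences."""
    modern_idx = [i for i, m in enumerate(ALL_METHODS) if priority.is_modern(m)]
    return np.asarray(raked, dtype=float)[modern_idx].sum(axis=0)


def compute_unmet(nonuser_need_share, cpr) -> np.ndarray:
    """Unmet need among all women: need share among non-users x (1 - CPR)."""
    return np.asarray(nonuser_need_share, dtype=float) * (1.0 - np.asarray(cpr, dtype=float))


def compute_demand_satisfied(mcpr, cpr, unmet) -> np.ndarray:
    """Share of need met with modern methods: mCPR / (CPR + unmet need).

    Defined as 0 where the denominator is 0 (no need at all; logged).
    """
    mcpr = np.asarray(mcpr, dtype=float)
    denom = np.asarray(cpr, dtype=float) + np.asarray(unmet, dtype=float)
    zero = denom == 0
    if np.any(zero):
        logger.info("demand satisfied: %d cell-draws with zero demand", int(np.sum(zero)))
    with np.errstate(divide="ignore", invalid="ignore"):
        ds = np.where(zero, 0.0, mcpr / np.where(zero, 1.0, denom))
    return ds


@dataclass
class ConsistentCellDraws:
    """Per-draw internally consistent indicator set for a block of cells.

    Arrays are (n_cells, n_draws); ``methods`` is (14, n_cells, n_draws)
    in the canonical method order.
    """

    cpr: np.ndarray
    methods: np.ndarray
    mcpr: np.ndarray
    unmet: np.ndarray
    demand_satisfied: np.ndarray

    def method_mix(self) -> np.ndarray:
        """Method shares of total use (method / CPR); NaN where CPR = 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.cpr > 0, self.methods / self.cpr, np.nan)


def make_consistent(
    cpr_draws: np.ndarray,
    method_draws: np.ndarray,
    need_share_draws: np.ndarray,
    priority: MethodPriority = DEFAULT_PRIORITY,
) -> ConsistentCellDraws:
    """Apply the full nesting to aligned draws.

    ``cpr_draws`` and ``need_share_draws``: (n_cells, n_draws);
    ``method_draws``: (14, n_cells, n_draws), aligned draw indices.
    """
    cpr = np.asarray(cpr_draws, dtype=float)
    methods = np.asarray(method_draws, dtype=float)
    need = np.asarray(need_share_draws, dtype=float)
    if methods.shape[0] != len(ALL_METHODS):
        raise ValueError("method_draws must have the 14 methods on axis 0")
    if methods.shape[1:] != cpr.shape or need.shape != cpr.shape:
        raise ValueError("misaligned draw arrays across quantities")
    raked = rake_methods_to_cpr(methods, cpr)
    mcpr = compute_mcpr(raked, priority)
    unmet = compute_unmet(need, cpr)
    ds = compute_demand_satisfied(mcpr, cpr, unmet)
    return ConsistentCellDraws(
        cpr=cpr, methods=raked, mcpr=mcpr, unmet=unmet, demand_satisfied=ds
    )
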