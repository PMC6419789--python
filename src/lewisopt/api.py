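"""High-level entry points tying the problem setup to the optimizers."""

from __future__ import annotations

from typing import Optional

from .interface import RunConfig
from .molgraph import MolecularGraph, positions, preplace
from .opt_astar import astar_search
from .opt_fpt import ResonanceSet, decompose, enumerate_minima, fpt_search
from .opt_local import minimise_local
from .scoring import AssignmentResult, ScoreTable, default_table, load_score_table


def _table_for(config: RunConfig) -> ScoreTable:
    if config.score_table_path:
        return load_score_table(config.score_table_path,
                                swap_c0_cminus=config.swap_c0_cminus)
    return default_table(swap_c0_cminus=config.swap_c0_cminus)


def _setup(g: MolecularGraph, config: RunConfig):
    p = positions(g, pair_mode=config.pair_mode)
    fixed = None
    if config.preplace:
        fixed, p, warned = preplace(g, p)
        if warned:
            fixed = None
    return p, fixed or {}


def assign(g: MolecularGraph, table: Optional[ScoreTable] = None,
           config: Optional[RunConfig] = None, **kwargs) -> AssignmentResult:
    """Optimal (or, for ``local``, locally optimal) electron assignment.

    ``kwargs`` override individual :class:`RunConfig` fields, e.g.
    ``assign(g, algorithm="astar")``.
    """
    config = config or RunConfig(**kwargs)
    table = table or _table_for(config)
    p, fixed = _setup(g, config)
    if config.algorithm == "local":
        return minimise_local(g, p, table, timeout_s=config.local_timeout_s,
                              fixed=fixed)
    if config.algorithm == "astar":
        return astar_search(g, p, table, memory_limit_mb=config.astar_memory_mb,
                            fixed=fixed, local_timeout_s=config.local_timeout_s)
    return fpt_search(g, p, table, fixed=fixed)


def resonance_structures(g: MolecularGraph, table: Optional[ScoreTable] = None,
                         config: Optional[RunConfig] = None,
                         **kwargs) -> ResonanceSet:
    """All (up to ``max_resonance``) minimum-score structures, via the DP."""
    config = config or RunConfig(**kwargs)
    table = table or _table_for(config)
    p, fixed = _setup(g, config)
    ntd = decompose(g)
    return enumerate_minima(g, p, table, ntd, cap=config.max_resonance,
                            fixed=fixed)
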