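"""Per-target subnetwork ensembles and whole-network edge statistics.

For every target gene the search repeatedly draws a regulator subset
(1..K_max genes, signs drawn per regulator), fits the dynamics model to
the target's profile and keeps the subnetwork if the variance-weighted
error is below the acceptance threshold (0.75).  Whole putative networks
are then assembled by sampling one accepted member per target (1,000
networks by default) and pooled into per-edge statistics: the confidence
metric (appearance frequency), sign fractions and a sign call.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .dynamics import (
    ACCEPTANCE_THRESHOLD,
    DEFAULT_VARIANCE,
    DynamicsModel,
    FitResult,
    fit_subset,
    simulate,
    weighted_error,
)
from .expression import ExpressionMatrix

__all__ = [
    "SearchConfig",
    "SubnetworkEnsemble",
    "EdgeStat",
    "build_ensemble",
    "build_all_ensembles",
    "sample_networks",
    "edge_statistics",
    "ensemble_edge_frequencies",
    "ensembles_to_frame",
]

log = logging.getLogger(__name__)

ACTIVATION = "activation"
INHIBITION = "inhibition"


@dataclass
class SearchConfig:
    """Knobs of the per-target subnetwork search."""

    k_max: int = 3                      # max regulators per subnetwork
    ensemble_cap: int = 200             # stop after this many accepted members
    attempt_budget: int = 1000          # max subsets tried per target
    acceptance_threshold: float = ACCEPTANCE_THRESHOLD
    variances: float | np.ndarray = DEFAULT_VARIANCE
    hill: float = 2.0
    substeps: int = 4
    n_starts: int = 3
    n_iter: int = 120
    allow_self_regulation: bool = False
    #: when True, accepted members are reduced to a necessary regulator
    #: set: a drawn regulator is dropped when removing it leaves the
    #: member data-consistent AND costs almost nothing (below
    #: prune_tolerance), i.e. it was a passenger of the draw
    prune_unnecessary: bool = True
    prune_tolerance: float = 0.05


@dataclass
class SubnetworkEnsemble:
    target: str
    members: list[FitResult] = field(default_factory=list)
    search_budget: int = 0

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class EdgeStat:
    source: str
    target: str
    confidence: float
    frac_activation: float
    frac_inhibition: float
    sign_call: str          # "activating" | "inhibiting" | "unclear"


def _params_to_model(target, act_genes, inh_genes, params, hill) -> DynamicsModel:
    m_a = len(act_genes)
    m_i = len(inh_genes)
    return DynamicsModel(
        target=target,
        activators=dict(zip(act_genes, params[:m_a])),
        inhibitors=dict(zip(inh_genes, params[m_a:m_a + m_i])),
        basal=float(params[m_a + m_i]),
        v_max=float(params[m_a + m_i + 1]),
        decay=float(params[m_a + m_i + 2]),
        hill=hill,
    )


def _prune_member(model, err, obs, times, profiles, cfg):
    """Reduce an accepted member to a necessary regulator set.

    Greedy leave-one-out: starting from the weakest weight, a regulator
    is removed whenever the reduced model remains data-consistent.  This
    keeps confidence statistics about regulators that actually carry the
    fit, not passengers of an under-determined draw.
    """
    from dataclasses import replace as _dc_replace

    traj = simulate(model, obs[0], times, profiles, cfg.substeps)
    if not cfg.prune_unnecessary:
        return model, err, traj
    current, cur_err, cur_traj = model, err, traj
    changed = True
    while changed and current.regulators:
        changed = False
        order = sorted(
            [(w, g, "a") for g, w in current.activators.items()]
            + [(w, g, "i") for g, w in current.inhibitors.items()])
        for _w, g, kind in order:
            if kind == "a":
                cand = _dc_replace(
                    current,
                    activators={k: v for k, v in current.activators.items()
                                if k != g})
            else:
                cand = _dc_replace(
                    current,
                    inhibitors={k: v for k, v in current.inhibitors.items()
                                if k != g})
            ctraj = simulate(cand, obs[0], times, profiles, cfg.substeps)
            cerr = weighted_error(ctraj, obs, cfg.variances)
            # a passenger's removal is nearly free; a real co-regulator's
            # removal degrades the fit even if it stays below threshold
            if (cerr < cfg.acceptance_threshold
                    and cerr <= cur_err + cfg.prune_tolerance):
                current, cur_err, cur_traj = cand, cerr, ctraj
                changed = True
                break
    return current, cur_err, cur_traj


def build_ensemble(
    target: str,
    m: ExpressionMatrix,
    cfg: SearchConfig | None = None,
    seed: int = 0,
) -> SubnetworkEnsemble:
    """Search regulator subsets for one target until cap or budget.

    Deterministic for a given seed: the subset draws come from one
    numpy Generator and every fit derives its own stream from it.
    """
    cfg = cfg or SearchConfig()
    if target not in m.values.index:
        raise KeyError(f"target {target!r} not in matrix")
    rng = np.random.default_rng(seed)
    candidates = [g for g in m.gene_ids
                  if cfg.allow_self_regulation or g != target]
    obs = m.profile(target)
    times = np.arange(m.n_stages, dtype=float)
    profiles = {g: m.profile(g) for g in candidates}
    ens = SubnetworkEnsemble(target=target)
    attempts = 0
    while attempts < cfg.attempt_budget and len(ens.members) < cfg.ensemble_cap:
        attempts += 1
        k = int(rng.integers(1, min(cfg.k_max, len(candidates)) + 1))
        subset = list(rng.choice(len(candidates), size=k, replace=False))
        signs = rng.random(k) < 0.5    # True -> activator
        act = [candidates[i] for i, s in zip(subset, signs) if s]
        inh = [candidates[i] for i, s in zip(subset, signs) if not s]
        act_prof = (np.vstack([profiles[g] for g in act])
                    if act else np.empty((0, m.n_stages)))
        inh_prof = (np.vstack([profiles[g] for g in inh])
                    if inh else np.empty((0, m.n_stages)))
        fit_seed = int(rng.integers(0, 2**31 - 1))
        params, err = fit_subset(
            target, obs, times, act_prof, inh_prof,
            variances=cfg.variances, hill=cfg.hill, substeps=cfg.substeps,
            n_starts=cfg.n_starts, n_iter=cfg.n_iter,
            early_stop=cfg.acceptance_threshold, seed=fit_seed,
        )
        if err < cfg.acceptance_threshold and np.isfinite(err):
            model = _params_to_model(target, act, inh, params, cfg.hill)
            model, err, traj = _prune_member(model, err, obs, times,
                                             profiles, cfg)
            ens.members.append(FitResult(model=model, error=err,
                                         accepted=True, trajectory=traj))
    ens.search_budget = attempts
    if not ens.members:
        warnings.warn(f"no accepted subnetworks for {target!r} "
                      f"within budget {cfg.attempt_budget}", stacklevel=2)
    return ens


def build_all_ensembles(
    m: ExpressionMatrix,
    cfg: SearchConfig | None = None,
    seed: int = 0,
) -> dict[str, SubnetworkEnsemble]:
    """One ensemble per gene; per-gene streams derive from the master seed.

    Each gene's stream is seeded independently of iteration order, so
    results merge deterministically however the per-gene tasks are run.
    """
    master = np.random.SeedSequence(seed)
    genes = m.gene_ids
    children = master.spawn(len(genes))
    out: dict[str, SubnetworkEnsemble] = {}
    for gene, child in zip(genes, children):
        gene_seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
        out[gene] = build_ensemble(gene, m, cfg, seed=gene_seed)
        log.info("ensemble %s: %d members / %d attempts",
                 gene, len(out[gene]), out[gene].search_budget)
    return out


def ensembles_to_frame(ensembles: dict[str, SubnetworkEnsemble]):
    """Flatten ensembles into one row per accepted member (TSV dump).

    Regulators are serialized as ``+gene`` (activator) / ``-gene``
    (inhibitor), parameters as ``name=value`` pairs.
    """
    import pandas as pd

    rows = []
    for gene in sorted(ensembles):
        ens = ensembles[gene]
        for i, member in enumerate(ens.members):
            mdl = member.model
            regs = ";".join([f"+{g}" for g in sorted(mdl.activators)]
                            + [f"-{g}" for g in sorted(mdl.inhibitors)])
            params = ";".join(
                [f"a[{g}]={w:.6g}" for g, w in sorted(mdl.activators.items())]
                + [f"c[{g}]={w:.6g}" for g, w in sorted(mdl.inhibitors.items())]
                + [f"b={mdl.basal:.6g}", f"v_max={mdl.v_max:.6g}",
                   f"d={mdl.decay:.6g}", f"h={mdl.hill:.6g}"])
            rows.append({"target": gene, "member_id": i, "regulators": regs,
                         "parameters": params, "error": member.error})
    return pd.DataFrame(rows, columns=["target", "member_id", "regulators",
                                       "parameters", "error"])


def _member_edges(ens: SubnetworkEnsemble, idx: int):
    model = ens.members[idx].model
    for g in model.activators:
        yield (g, ens.target, ACTIVATION)
    for g in model.inhibitors:
        yield (g, ens.target, INHIBITION)


def sample_networks(
    ensembles: dict[str, SubnetworkEnsemble],
    n_networks: int = 1000,
    seed: int = 0,
) -> list[list[tuple[str, str, str]]]:
    """Assemble putative whole networks, one member per non-empty ensemble.

    Returns a list of networks, each a list of (source, target, sign).
    """
    non_empty = {g: e for g, e in ensembles.items() if len(e) > 0}
    if not non_empty:
        raise ValueError("all ensembles are empty")
    rng = np.random.default_rng(seed)
    networks: list[list[tuple[str, str, str]]] = []
    for _ in range(n_networks):
        edges: list[tuple[str, str, str]] = []
        for gene in sorted(non_empty):
            ens = non_empty[gene]
            idx = int(rng.integers(0, len(ens)))
            edges.extend(_member_edges(ens, idx))
        networks.append(edges)
    return networks


def edge_statistics(
    networks: list[list[tuple[str, str, str]]],
    sign_majority: float = 2 / 3,
) -> list[EdgeStat]:
    """Pool sampled networks into per-directed-edge statistics."""
    if not networks:
        raise ValueError("need at least one network")
    n = len(networks)
    counts: dict[tuple[str, str], list[int]] = {}
    for net in networks:
        for src, tgt, sign in net:
            rec = counts.setdefault((src, tgt), [0, 0])
            rec[0] += 1
            if sign == ACTIVATION:
                rec[1] += 1
    stats = []
    for (src, tgt), (total, n_act) in sorted(counts.items()):
        fa = n_act / total
        fi = 1.0 - fa
        call = ("activating" if fa >= sign_majority
                else "inhibiting" if fi >= sign_majority
                else "unclear")
        stats.append(EdgeStat(source=src, target=tgt, confidence=total / n,
                              frac_activation=fa, frac_inhibition=fi,
                              sign_call=call))
    return stats


def ensemble_edge_frequencies(
    ensembles: dict[str, SubnetworkEnsemble],
) -> dict[tuple[str, str], float]:
    """Per-edge appearance frequency directly over ensemble members.

    The sampled-network confidence converges to these frequencies as the
    number of sampled networks grows; useful as the exact reference.
    """
    out: dict[tuple[str, str], float] = {}
    for gene, ens in ensembles.items():
        if not ens.members:
            continue
        n = len(ens.members)
        tally: dict[tuple[str, str], int] = {}
        for i in range(n):
            for src, tgt, _sign in _member_edges(ens, i):
                tally[(src, tgt)] = tally.get((src, tgt), 0) + 1
        for edge, cnt in tally.items():
            out[edge] = cnt / n
    return out
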