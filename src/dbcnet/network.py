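"""Builder for the two-hypercolumn columnar microcircuit.

The network nests hypercolumns (HCs) holding minicolumns (MCs) of pyramidal
cells with shared stimulus selectivity.  Each HC has one pool of basket
cells implementing soft winner-take-all feedback inhibition, and each MC
contains exactly one double bouquet cell (DBC) that inhibits every pyramidal
cell of its own MC.  MCs are partitioned into coactive groups (by default
{MC0, MC2} vs {MC1, MC3}, one member per HC); groups compete.

Projections (Bernoulli wiring, reproducible from the spec's seed):

1. plastic depressing AMPA pyr->pyr recurrent within each MC (p = 0.20)
2. plastic AMPA pyr->pyr between coactive MCs across HCs (p = 0.20)
3. plastic AMPA pyr->DBC from each MC onto the DBCs of all *competing*
   MCs, within and between HCs (p = 0.20)
4. static AMPA pyr->basket within each HC (p = 0.70)
5. static GABA basket->pyr within each HC (p = 0.70)
6. static GABA DBC->pyr onto every pyramidal cell of the DBC's own MC

There are no pyr->pyr connections between competing MCs: their interaction
is exclusively disynaptic (basket cells within an HC, DBCs within and
between HCs), which is what keeps every learned excitatory weight
non-negative and the circuit compliant with Dale's principle.

Conduction delays are 1.5 ms within an HC and 4.5 ms between HCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import params as default_params
from .errors import ConfigurationError
from .neurons import NeuronParams

__all__ = ["NetworkSpec", "Projection", "Network", "build", "competing_mcs",
           "dale_violations"]


@dataclass(frozen=True)
class NetworkSpec:
    """Declarative topology of the columnar network.

    MC ids are global: ``mc = hc * n_mc_per_hc + local_index``.
    ``coactive_groups`` partitions all MC ids into stimulus-selective
    groups; MCs in different groups compete.
    """

    n_hc: int = 2
    n_mc_per_hc: int = 2
    n_pyr_per_mc: int = 30
    n_basket_per_hc: int = 8
    n_dbc_per_mc: int = 1
    p_plastic: float = 0.20
    p_basket: float = 0.70
    delay_within_hc: float = 1.5
    delay_between_hc: float = 4.5
    coactive_groups: tuple[tuple[int, ...], ...] = ((0, 2), (1, 3))
    rng_seed: int = 0

    def __post_init__(self) -> None:
        errs = []
        if self.n_hc < 1 or self.n_mc_per_hc < 1 or self.n_pyr_per_mc < 1:
            errs.append("network sizes must be positive")
        if self.n_dbc_per_mc != 1:
            errs.append("network.n_dbc_per_mc: exactly one DBC per MC")
        for name, p in (("p_plastic", self.p_plastic), ("p_basket", self.p_basket)):
            if not (0.0 <= p <= 1.0):
                errs.append(f"network.{name}: probability {p} outside [0, 1]")
        if self.delay_within_hc <= 0 or self.delay_between_hc <= 0:
            errs.append("network delays must be positive")
        all_mcs = sorted(m for g in self.coactive_groups for m in g)
        if all_mcs != list(range(self.n_mc)):
            errs.append("network.coactive_groups: must partition all MC ids")
        for g in self.coactive_groups:
            by_hc: dict[int, int] = {}
            for m in g:
                by_hc[m // self.n_mc_per_hc] = by_hc.get(m // self.n_mc_per_hc, 0) + 1
            if any(c > 1 for c in by_hc.values()):
                errs.append("network.coactive_groups: groups within an HC "
                            "must be disjoint (one MC per HC per group)")
        if errs:
            raise ConfigurationError("; ".join(errs))

    @property
    def n_mc(self) -> int:
        return self.n_hc * self.n_mc_per_hc

    def hc_of_mc(self, mc: int) -> int:
        return mc // self.n_mc_per_hc

    def group_of_mc(self, mc: int) -> int:
        for gi, g in enumerate(self.coactive_groups):
            if mc in g:
                return gi
        raise ConfigurationError(f"unknown MC id {mc}")

    def delay(self, mc_pre: int, mc_post: int) -> float:
        same_hc = self.hc_of_mc(mc_pre) == self.hc_of_mc(mc_post)
        return self.delay_within_hc if same_hc else self.delay_between_hc


def competing_mcs(spec: NetworkSpec, mc: int) -> list[int]:
    """All MC ids (across both HCs) outside ``mc``'s coactive group."""
    if not (0 <= mc < spec.n_mc):
        raise ConfigurationError(f"unknown MC id {mc}")
    gi = spec.group_of_mc(mc)
    return sorted(m for g_idx, g in enumerate(spec.coactive_groups)
                  for m in g if g_idx != gi)


@dataclass
class Projection:
    """One realized connection group; ``pre``/``post`` are synapse-level
    neuron-id arrays (one entry per connection)."""

    name: str
    kind: str                # key into the projection parameter table
    pre: np.ndarray
    post: np.ndarray
    receptor: str            # 'ampa' | 'gaba'
    delay: float             # ms
    plastic: bool
    depressing: bool
    weight: float            # static weight (nS), ignored if plastic
    g_gain: float            # nS per unit BCPNN weight
    u: float
    tau_rec: float

    @property
    def n_connections(self) -> int:
        return len(self.pre)


@dataclass
class Network:
    spec: NetworkSpec
    n_neurons: int
    cell_class: np.ndarray                    # per-neuron 'pyr'/'basket'/'dbc'
    populations: dict[str, np.ndarray]        # label -> neuron ids
    projections: list[Projection]
    neuron_params: dict[str, NeuronParams] = field(default_factory=dict)

    def population(self, label: str) -> np.ndarray:
        if label not in self.populations:
            raise ConfigurationError(f"unknown population {label!r}")
        return self.populations[label]

    def projection(self, name: str) -> Projection:
        for p in self.projections:
            if p.name == name:
                return p
        raise ConfigurationError(f"unknown projection {name!r}")

    def edge_table(self) -> pd.DataFrame:
        """All realized connections as (pre, post, projection, delay, type)."""
        frames = [
            pd.DataFrame({
                "pre": p.pre, "post": p.post, "projection": p.name,
                "delay": p.delay, "receptor": p.receptor, "plastic": p.plastic,
            })
            for p in self.projections
        ]
        return pd.concat(frames, ignore_index=True)


def _bernoulli_pairs(rng, pre_ids, post_ids, p, allow_self=False):
    """Draw each ordered (pre, post) pair independently with probability p;
    no autapses, no multapses."""
    if p <= 0 or len(pre_ids) == 0 or len(post_ids) == 0:
        return np.empty(0, int), np.empty(0, int)
    mask = rng.random((len(pre_ids), len(post_ids))) < p
    if not allow_self:
        same = pre_ids[:, None] == post_ids[None, :]
        mask &= ~same
    ii, jj = np.nonzero(mask)
    return pre_ids[ii], post_ids[jj]


def build(
    spec: NetworkSpec,
    neuron_params: dict[str, NeuronParams] | None = None,
    projection_params: dict[str, dict] | None = None,
) -> Network:
    """Realize the columnar network from its spec.

    Wiring is reproducible: identical spec (including ``rng_seed``) gives
    identical edge lists.  ``projection_params`` overrides entries of the
    default per-kind synapse table.
    """
    neuron_params = dict(default_params.NEURON_DEFAULTS, **(neuron_params or {}))
    proj_table = {k: dict(v) for k, v in default_params.PROJECTION_DEFAULTS.items()}
    for k, v in (projection_params or {}).items():
        if k not in proj_table:
            raise ConfigurationError(f"synapses.{k}: unknown projection kind")
        proj_table[k].update(v)

    rng = np.random.default_rng(spec.rng_seed)

    # ---- populations ----------------------------------------------------
    populations: dict[str, np.ndarray] = {}
    classes: list[str] = []
    next_id = 0

    def alloc(n: int, cls: str) -> np.ndarray:
        nonlocal next_id
        ids = np.arange(next_id, next_id + n)
        next_id += n
        classes.extend([cls] * n)
        return ids

    for mc in range(spec.n_mc):
        populations[f"pyr_mc{mc}"] = alloc(spec.n_pyr_per_mc, "pyr")
    for hc in range(spec.n_hc):
        populations[f"basket_hc{hc}"] = alloc(spec.n_basket_per_hc, "basket")
    for mc in range(spec.n_mc):
        populations[f"dbc_mc{mc}"] = alloc(spec.n_dbc_per_mc, "dbc")
    for hc in range(spec.n_hc):
        mcs = range(hc * spec.n_mc_per_hc, (hc + 1) * spec.n_mc_per_hc)
        populations[f"pyr_hc{hc}"] = np.concatenate(
            [populations[f"pyr_mc{m}"] for m in mcs])

    projections: list[Projection] = []

    def add(name: str, kind: str, pre: np.ndarray, post: np.ndarray, delay: float):
        cfg = proj_table[kind]
        projections.append(Projection(
            name=name, kind=kind, pre=pre, post=post,
            receptor=cfg["receptor"], delay=delay, plastic=cfg["plastic"],
            depressing=cfg["depressing"], weight=cfg["weight"],
            g_gain=cfg["g_gain"], u=cfg["u"], tau_rec=cfg["tau_rec"],
        ))

    # ---- plastic projections -------------------------------------------
    for mc in range(spec.n_mc):
        pyr = populations[f"pyr_mc{mc}"]
        pre, post = _bernoulli_pairs(rng, pyr, pyr, spec.p_plastic)
        add(f"pyr_mc{mc}->pyr_mc{mc}", "pyr_pyr_recurrent", pre, post,
            spec.delay_within_hc)

    for group in spec.coactive_groups:
        for a in group:
            for b in group:
                if a == b:
                    continue
                pre, post = _bernoulli_pairs(
                    rng, populations[f"pyr_mc{a}"], populations[f"pyr_mc{b}"],
                    spec.p_plastic)
                add(f"pyr_mc{a}->pyr_mc{b}", "pyr_pyr_associative", pre, post,
                    spec.delay(a, b))

    for mc in range(spec.n_mc):
        for target in competing_mcs(spec, mc):
            pre, post = _bernoulli_pairs(
                rng, populations[f"pyr_mc{mc}"], populations[f"dbc_mc{target}"],
                spec.p_plastic)
            add(f"pyr_mc{mc}->dbc_mc{target}", "pyr_dbc", pre, post,
                spec.delay(mc, target))

    # ---- static projections --------------------------------------------
    for hc in range(spec.n_hc):
        pyr = populations[f"pyr_hc{hc}"]
        basket = populations[f"basket_hc{hc}"]
        pre, post = _bernoulli_pairs(rng, pyr, basket, spec.p_basket)
        add(f"pyr_hc{hc}->basket_hc{hc}", "pyr_basket", pre, post,
            spec.delay_within_hc)
        pre, post = _bernoulli_pairs(rng, basket, pyr, spec.p_basket)
        add(f"basket_hc{hc}->pyr_hc{hc}", "basket_pyr", pre, post,
            spec.delay_within_hc)

    for mc in range(spec.n_mc):
        dbc = populations[f"dbc_mc{mc}"]
        pyr = populations[f"pyr_mc{mc}"]
        pre = np.repeat(dbc, len(pyr))
        post = np.tile(pyr, len(dbc))
        add(f"dbc_mc{mc}->pyr_mc{mc}", "dbc_pyr", pre, post,
            spec.delay_within_hc)

    return Network(
        spec=spec,
        n_neurons=next_id,
        cell_class=np.array(classes),
        populations=populations,
        projections=projections,
        neuron_params=neuron_params,
    )


_RECEPTOR_OF_CLASS = {"pyr": "ampa", "basket": "gaba", "dbc": "gaba"}


def dale_violations(network: Network) -> list[str]:
    """Audit Dale's principle on the wiring: every neuron's outgoing
    projections must all use the receptor of its class (pyramidal -> AMPA,
    basket/DBC -> GABA).  Returns a list of human-readable violations
    (empty when compliant)."""
    out = []
    for proj in network.projections:
        if len(proj.pre) == 0:
            continue
        pre_classes = set(network.cell_class[proj.pre])
        for cls in pre_classes:
            expected = _RECEPTOR_OF_CLASS[cls]
            if proj.receptor != expected:
                out.append(
                    f"{proj.name}: {cls} neurons project via {proj.receptor}, "
                    f"expected {expected}"
                )
    return out
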