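"""YAML configuration helpers for the command-line interface.

A design config names the randomization method and its parameters::

    method: permuted_blocks
    allocation: "2:1"
    params: {block_size: 6, stratified: true}

A model config lists the adjustment terms and the trial-table columns::

    terms: [intercept, {factor: stratum1}, {covariate: age}]
    y: y
    delta: delta
    strata: [stratum1, stratum2]
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .designs import (AllocationSpec, make_biased_coin_2to1, make_complete,
                      make_efron_coin_1to1, make_marginal_balance_2to1,
                      make_multiarm_complete, make_multiarm_permuted_blocks,
                      make_permuted_blocks, make_pocock_simon_1to1,
                      make_sequential_combine, make_urn_2to1)
from .projection import DesignMatrixSpec

__all__ = ["design_from_config", "xspec_from_config", "load_yaml"]


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def design_from_config(cfg: dict):
    method = cfg["method"]
    alloc = AllocationSpec.parse(cfg.get("allocation", "1:1"))
    params = dict(cfg.get("params") or {})
    if method == "complete":
        return make_complete(alloc)
    if method == "permuted_blocks":
        return make_permuted_blocks(alloc, **params)
    if method == "biased_coin_2to1":
        return make_biased_coin_2to1(**params)
    if method == "marginal_balance_2to1":
        return make_marginal_balance_2to1(**params)
    if method == "urn_2to1":
        return make_urn_2to1(**params)
    if method == "efron_coin_1to1":
        return make_efron_coin_1to1(**params)
    if method == "pocock_simon_1to1":
        return make_pocock_simon_1to1(**params)
    if method == "sequential_combine":
        inner_cfg = params.pop("inner", {"method": "multiarm_permuted_blocks",
                                         "params": {"block_size": alloc.r1 + alloc.r2}})
        inner_params = dict(inner_cfg.get("params") or {})
        k = alloc.r1 + alloc.r2
        if inner_cfg.get("method", "multiarm_permuted_blocks") == "multiarm_complete":
            inner = make_multiarm_complete(k)
        else:
            inner = make_multiarm_permuted_blocks(k, **inner_params)
        return make_sequential_combine(inner, alloc)
    raise ValueError(f"unknown randomization method {method!r}")


def xspec_from_config(cfg: dict) -> DesignMatrixSpec:
    terms = []
    for t in cfg.get("terms", ["intercept"]):
        if t in ("intercept", "1", 1):
            terms.append("intercept")
        elif isinstance(t, dict) and "factor" in t:
            terms.append(("factor", t["factor"]))
        elif isinstance(t, dict) and "covariate" in t:
            terms.append(("covariate", t["covariate"]))
        else:
            raise ValueError(f"unrecognized model term {t!r}")
    return DesignMatrixSpec(terms)
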