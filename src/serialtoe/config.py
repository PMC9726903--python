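"""Structured (YAML) configuration for designs and observer parameters.

Every free number of the simulation — noise schedules, truncation
bounds, prior initialization, design geometry — lives in a config file;
``serialtoe/data/default_params.yml`` ships the package defaults that
reproduce the qualitative time-order-error pattern.
"""

from __future__ import annotations

import dataclasses
import math
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from .design import DesignSpec
from .observer import ObserverParams, TruncatedNormal

_INF = float("inf")


def _tn_to_dict(tn: TruncatedNormal) -> dict[str, float]:
    d = {"loc": tn.loc, "scale": tn.scale}
    if math.isfinite(tn.lower):
        d["lower"] = tn.lower
    if math.isfinite(tn.upper):
        d["upper"] = tn.upper
    return d


def _tn_from_dict(d: dict[str, Any]) -> TruncatedNormal:
    return TruncatedNormal(
        loc=float(d.get("loc", 0.0)),
        scale=float(d.get("scale", 1.0)),
        lower=float(d.get("lower", -_INF)),
        upper=float(d.get("upper", _INF)),
    )


def params_to_dict(params: ObserverParams, spec: DesignSpec | None = None) -> dict:
    out: dict[str, Any] = {
        "observer": {
            "q": params.q,
            "sigma_subject": _tn_to_dict(params.sigma_subject),
            "noise_floor_ms": params.noise_floor_ms,
            "isi_noise": {float(k): float(v) for k, v in params.isi_noise.items()},
            "longer_first_noise": _tn_to_dict(params.longer_first_noise),
            "longer_second_noise": _tn_to_dict(params.longer_second_noise),
            "weak_level_noise": _tn_to_dict(params.weak_level_noise),
            "weak_delta": params.weak_delta,
            "prior": {
                "mean0": params.prior_mean0,
                "var0": params.prior_var0,
                "carryover": params.prior_carryover,
            },
        }
    }
    if spec is not None:
        out["design"] = {
            "s_duration": spec.s_duration,
            "deltas": list(spec.deltas),
            "isis": list(spec.isis),
            "trials_per_block": spec.trials_per_block,
            "iti_range": list(spec.iti_range),
        }
    return out


def params_from_dict(d: dict) -> tuple[ObserverParams, DesignSpec]:
    obs = d.get("observer", {})
    prior = obs.get("prior", {})
    params = ObserverParams(
        q=float(obs.get("q", 1.5)),
        sigma_subject=_tn_from_dict(obs.get("sigma_subject", {"loc": 0.25, "scale": 0.0})),
        noise_floor_ms=float(obs.get("noise_floor_ms", 0.0)),
        isi_noise={float(k): float(v) for k, v in obs.get("isi_noise", {}).items()}
        or ObserverParams().isi_noise,
        longer_first_noise=_tn_from_dict(obs.get("longer_first_noise", {})),
        longer_second_noise=_tn_from_dict(obs.get("longer_second_noise", {})),
        weak_level_noise=_tn_from_dict(obs.get("weak_level_noise", {})),
        weak_delta=float(obs.get("weak_delta", 20.0)),
        prior_mean0=float(prior.get("mean0", math.log(120.0))),
        prior_var0=float(prior.get("var0", 10.0)),
        prior_carryover=bool(prior.get("carryover", True)),
    )
    des = d.get("design", {})
    spec = DesignSpec(
        s_duration=float(des.get("s_duration", 120.0)),
        deltas=tuple(float(x) for x in des.get("deltas", (20.0, 60.0, 100.0))),
        isis=tuple(float(x) for x in des.get("isis", (400.0, 800.0, 1600.0, 2000.0))),
        trials_per_block=int(des.get("trials_per_block", 120)),
        iti_range=tuple(float(x) for x in des.get("iti_range", (1000.0, 3000.0))),
    )
    return params, spec


def save_params(path: str | Path, params: ObserverParams, spec: DesignSpec | None = None) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_dict(params, spec), fh, sort_keys=False)


def load_params(path: str | Path) -> tuple[ObserverParams, DesignSpec]:
    with open(path) as fh:
        return params_from_dict(yaml.safe_load(fh))


def default_params() -> tuple[ObserverParams, DesignSpec]:
    """The packaged default observer configuration and session design."""
    text = resources.files("serialtoe").joinpath("data/default_params.yml").read_text()
    return params_from_dict(yaml.safe_load(text))


def null_params() -> tuple[ObserverParams, DesignSpec]:
    """A symmetric control configuration: same subject noise as the
    defaults but duration-independent encoding (no noise floor), unit
    ISI multipliers and standard-normal noise shapes everywhere, so no
    time-order error should emerge."""
    params, spec = default_params()
    sym = dataclasses.replace(
        params,
        noise_floor_ms=0.0,
        isi_noise={k: 1.0 for k in params.isi_noise},
        longer_first_noise=TruncatedNormal(0.0, 1.0),
        longer_second_noise=TruncatedNormal(0.0, 1.0),
        weak_level_noise=TruncatedNormal(0.0, 1.0),
    )
    return sym, spec
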