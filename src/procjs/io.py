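"""File formats, configuration parsing, fixtures and run manifests.

Conventions: occasions are 1-based in every file (occasion 1 is the first
release occasion; interval t spans occasions t -> t+1).  Encounter histories
are CSV with one row per individual: ``id, release_occasion,
age_at_release`` (``juv`` or ``ad``), then T columns ``y1..yT`` of 0/1.
M-arrays are one CSV per age class with labeled re-encounter columns and a
``never`` column.  Every CLI run writes a JSON manifest recording the config
hash, seeds, package version and input/output paths.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from .marray import AgeMArraySet, build_marrays
from .priors import SeparatedPriorConfig, WishartPriorConfig
from .sampling import MCMCConfig
from .simulate import (
    _AGE_CODES,
    _AGE_LABELS,
    AnnualRates,
    EncounterHistorySet,
    SimulationConfig,
    simulate_dataset,
)

__all__ = [
    "write_histories",
    "read_histories",
    "write_rates",
    "read_rates",
    "write_marrays",
    "read_marrays",
    "parse_config",
    "serialize_config",
    "RunManifest",
    "generate_fixtures",
]


# ----------------------------------------------------------------------
# encounter histories
def write_histories(histories: EncounterHistorySet, path) -> None:
    T = histories.n_occasions
    df = pd.DataFrame(
        histories.y, columns=[f"y{t}" for t in range(1, T + 1)]
    )
    df.insert(0, "age_at_release", [_AGE_LABELS[a] for a in histories.age_at_release])
    df.insert(0, "release_occasion", histories.tau + 1)
    df.insert(0, "id", np.arange(1, len(df) + 1))
    df.to_csv(path, index=False)


def read_histories(path) -> EncounterHistorySet:
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError(f"{path}: no encounter histories")
    ycols = sorted(
        [c for c in df.columns if c.startswith("y") and c[1:].isdigit()],
        key=lambda c: int(c[1:]),
    )
    if not ycols:
        raise ValueError(f"{path}: no detection columns y1..yT found")
    ages = []
    for i, code in enumerate(df["age_at_release"].astype(str)):
        if code not in _AGE_CODES:
            raise ValueError(f"{path}: unknown age code {code!r} in row {i}")
        ages.append(_AGE_CODES[code])
    return EncounterHistorySet(
        y=df[ycols].to_numpy(dtype=np.int8),
        tau=df["release_occasion"].to_numpy(dtype=np.int64) - 1,
        age_at_release=np.asarray(ages, dtype=np.int8),
    )


# ----------------------------------------------------------------------
# generating truth (for scoring simulated datasets)
def write_rates(rates: AnnualRates, path) -> None:
    df = pd.DataFrame(
        {
            "interval": np.arange(1, rates.n_intervals + 1),
            "phi_ad": rates.phi_ad,
            "phi_juv": rates.phi_juv,
            "logit_phi_ad": rates.logit_ad,
            "logit_phi_juv": rates.logit_juv,
            "rho_true": rates.rho_true,
        }
    )
    df.to_csv(path, index=False)


def read_rates(path) -> AnnualRates:
    df = pd.read_csv(path)
    return AnnualRates(
        phi_ad=df["phi_ad"].to_numpy(),
        phi_juv=df["phi_juv"].to_numpy(),
        logit_ad=df["logit_phi_ad"].to_numpy(),
        logit_juv=df["logit_phi_juv"].to_numpy(),
        rho_true=float(df["rho_true"].iloc[0]),
    )


# ----------------------------------------------------------------------
# m-arrays
def write_marrays(marr: AgeMArraySet, prefix: str) -> List[str]:
    paths = []
    for age in ("juv", "ad"):
        path = f"{prefix}_{age}.csv"
        marr.to_frame(age).to_csv(path, index=False)
        paths.append(path)
    return paths


def read_marrays(prefix: str) -> AgeMArraySet:
    juv = pd.read_csv(f"{prefix}_juv.csv")
    ad = pd.read_csv(f"{prefix}_ad.csv")
    return AgeMArraySet.from_frames(juv, ad)


# ----------------------------------------------------------------------
# configuration
_SECTION_TYPES = {
    "simulation": SimulationConfig,
    "mcmc": MCMCConfig,
}


def _build_prior_config(d: Dict):
    d = dict(d)
    kind = d.pop("parameterization", "separated")
    if kind == "iw":
        allowed = {f.name for f in dataclasses.fields(WishartPriorConfig)}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"priors: unknown keys {sorted(unknown)}")
        if "scale" in d:
            d["scale"] = np.asarray(d["scale"], dtype=float)
        return WishartPriorConfig(**d)
    if kind == "separated":
        allowed = {f.name for f in dataclasses.fields(SeparatedPriorConfig)}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"priors: unknown keys {sorted(unknown)}")
        return SeparatedPriorConfig(**d)
    raise ValueError(f"priors.parameterization must be 'iw' or 'separated', got {kind!r}")


def parse_config(path) -> Dict[str, object]:
    """Parse a YAML or JSON config file into validated typed configs.

    Recognized top-level sections: ``simulation``, ``mcmc``, ``priors``.
    Missing sections and keys fall back to the package defaults (mean logit
    survival 1 / -1, temporal variances 0.1, detection 0.5; two chains of
    25,000 iterations with 15,000 burn-in and thinning 5).  Unknown sections
    or keys are rejected with their key path.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    unknown = set(raw) - (set(_SECTION_TYPES) | {"priors"})
    if unknown:
        raise ValueError(f"{path}: unknown sections {sorted(unknown)}")
    out: Dict[str, object] = {}
    for section, cls in _SECTION_TYPES.items():
        payload = raw.get(section, {}) or {}
        allowed = {f.name for f in dataclasses.fields(cls)}
        bad = set(payload) - allowed
        if bad:
            raise ValueError(
                f"{path}: unknown keys {sorted(f'{section}.{k}' for k in bad)}"
            )
        try:
            out[section] = cls(**payload)
        except (TypeError, ValueError) as err:
            raise ValueError(f"{path}: invalid {section} config: {err}") from err
    out["priors"] = _build_prior_config(raw.get("priors", {}) or {})
    return out


def serialize_config(configs: Dict[str, object]) -> Dict:
    """Inverse of :func:`parse_config` (as a plain mapping)."""
    out: Dict[str, Dict] = {}
    for section in ("simulation", "mcmc"):
        out[section] = dataclasses.asdict(configs[section])
    pri = configs["priors"]
    d = dataclasses.asdict(pri)
    if isinstance(pri, WishartPriorConfig):
        d["scale"] = np.asarray(d["scale"]).tolist()
        d["parameterization"] = "iw"
    else:
        d["parameterization"] = "separated"
    out["priors"] = d
    return out


# ----------------------------------------------------------------------
# run manifests
@dataclass
class RunManifest:
    """Provenance record written next to every CLI output."""

    command: str
    config: Dict
    seeds: Dict[str, int]
    inputs: List[str] = field(default_factory=list)
    outputs: List[str] = field(default_factory=list)
    version: str = ""
    timestamp: str = ""
    config_hash: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        if not self.config_hash:
            payload = json.dumps(self.config, sort_keys=True, default=str).encode()
            self.config_hash = hashlib.sha256(payload).hexdigest()[:12]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


# ----------------------------------------------------------------------
# fixtures
def micro_histories() -> EncounterHistorySet:
    """Hand-checkable micro dataset: T = 3, five individuals.

    Histories (1-based occasions):
      1: juvenile released at 1, seen at 2 and 3
      2: juvenile released at 1, never seen again
      3: adult released at 1, seen at 3 only
      4: adult released at 2, never seen again
      5: adult released at 1, never seen again
    Its m-arrays can be enumerated by hand: juvenile array has M[1, 2] = 1
    (ind 1) and one never-seen at row 1 (ind 2); the adult array picks up
    ind 1 re-released at occasion 2 (seen at 3), ind 3 (row 1, seen at 3),
    and the never-seen inds 4 and 5.
    """
    y = np.array(
        [
            [1, 1, 1],
            [1, 0, 0],
            [1, 0, 1],
            [0, 1, 0],
            [1, 0, 0],
        ],
        dtype=np.int8,
    )
    tau = np.array([0, 0, 0, 1, 0])
    age = np.array([0, 0, 1, 1, 1], dtype=np.int8)
    return EncounterHistorySet(y=y, tau=tau, age_at_release=age)


def generate_fixtures(seed: int, out_dir: str) -> List[str]:
    """Write the bundled small datasets: a simulated T = 5, 50-release set
    and the hand-checkable T = 3 micro set, with their m-arrays."""
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    cfg = SimulationConfig(T=5, releases_per_occasion=50, rho=0.5, seed=None)
    hist, rates = simulate_dataset(cfg, seed=seed)
    p = os.path.join(out_dir, "small_histories.csv")
    write_histories(hist, p)
    paths.append(p)
    p = os.path.join(out_dir, "small_truth.csv")
    write_rates(rates, p)
    paths.append(p)
    paths.extend(write_marrays(build_marrays(hist), os.path.join(out_dir, "small_marray")))
    micro = micro_histories()
    p = os.path.join(out_dir, "micro_histories.csv")
    write_histories(micro, p)
    paths.append(p)
    paths.extend(
        write_marrays(build_marrays(micro), os.path.join(out_dir, "micro_marray"))
    )
    return paths
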