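"""File formats and run configuration.

Everything on disk is plain text: tidy CSV for samples and summaries (one
header line), JSON sidecars for trial metadata and manifests, YAML for run
configuration.  Positions are stored in meters in the machine-facing files;
the human-facing report tables carry explicit cm columns.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from .models import BisectionParams, Feedback, PsychophysicalLaw
from .preprocess import GroupSummary
from .simulate import (
    Condition,
    StiffnessGenerator,
    TrialDesign,
    TrialRecord,
)

__all__ = [
    "RunConfig",
    "write_records",
    "read_records",
    "write_group_summaries",
    "read_group_summaries",
    "write_manifest",
]


@dataclass
class RunConfig:
    """Configuration of one simulation run."""

    experiment: Literal["exp1", "exp2"] = "exp1"
    generator: Literal["bisection", "stiffness"] = "bisection"
    seed: int = 0
    n_participants: int = 12
    # bisection generator parameters (SI units)
    F_th: float = 0.085
    sigma_Fth: float = 0.052
    sigma_P_fp: float = 0.0093
    sigma_P_fa: float = 0.012
    # stiffness generator parameters
    beta: float = 0.8
    probe_force: float = 0.3
    sigma_P: float = 0.005
    trajectories: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.experiment not in ("exp1", "exp2"):
            raise ValueError(f"experiment must be exp1/exp2, got {self.experiment!r}")
        if self.generator not in ("bisection", "stiffness"):
            raise ValueError(f"unknown generator {self.generator!r}")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")

    def generator_params(self) -> BisectionParams | StiffnessGenerator:
        if self.generator == "bisection":
            if self.experiment == "exp1":
                return BisectionParams(self.F_th, self.sigma_Fth,
                                       self.sigma_P_fp, self.sigma_P_fa)
            return BisectionParams.unilateral(self.F_th, self.sigma_Fth,
                                              self.sigma_P)
        law = PsychophysicalLaw(beta=self.beta, F_th=self.F_th)
        return StiffnessGenerator(law, self.probe_force, self.sigma_P)


# ---------------------------------------------------------------------------
# Trial records
# ---------------------------------------------------------------------------

def _condition_dict(c: Condition) -> dict:
    return {"experiment": c.experiment, "K_left": c.K_left,
            "K_right": c.K_right, "feedback": c.feedback.value, "side": c.side}


def _condition_from_dict(d: dict) -> Condition:
    return Condition(d["experiment"], d["K_left"], d["K_right"],
                     Feedback(d["feedback"]), d["side"])


def _design_dict(d: TrialDesign) -> dict:
    return {"condition": _condition_dict(d.condition), "center_m": d.center,
            "start_m": d.start, "region_index": d.region_index, "tag": d.tag}


def _design_from_dict(d: dict) -> TrialDesign:
    return TrialDesign(_condition_from_dict(d["condition"]), d["center_m"],
                       d["start_m"], d["region_index"], d["tag"])


def write_records(records: list[TrialRecord], samples_csv: str | Path,
                  meta_json: str | Path) -> None:
    """Tidy samples CSV (one row per sample) + JSON design sidecar."""
    frames = []
    meta = []
    for i, r in enumerate(records):
        frames.append(pd.DataFrame({
            "trial": i, "t_s": r.t, "x_m": r.x, "F_N": r.F_measured,
            "quality_flag": r.quality_flag.astype(int)}))
        meta.append({"trial": i, "design": _design_dict(r.design),
                     "end_pressed_at_s": r.end_pressed_at})
    pd.concat(frames, ignore_index=True).to_csv(samples_csv, index=False)
    Path(meta_json).write_text(json.dumps(meta, indent=1))


def read_records(samples_csv: str | Path,
                 meta_json: str | Path) -> list[TrialRecord]:
    df = pd.read_csv(samples_csv)
    meta = json.loads(Path(meta_json).read_text())
    records = []
    for m in meta:
        g = df[df["trial"] == m["trial"]]
        records.append(TrialRecord(
            design=_design_from_dict(m["design"]),
            t=g["t_s"].to_numpy(), x=g["x_m"].to_numpy(),
            F_measured=g["F_N"].to_numpy(),
            quality_flag=g["quality_flag"].to_numpy().astype(bool),
            end_pressed_at=m["end_pressed_at_s"]))
    return records


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def write_group_summaries(summaries: list[GroupSummary],
                          path: str | Path) -> None:
    rows = []
    for s in summaries:
        c = s.condition
        rows.append({**_condition_dict(c),
                     "bias_m": s.bias, "se_m": s.se, "sd_m": s.sd,
                     "bias_cm": s.bias * 100.0, "sd_cm": s.sd * 100.0,
                     "n_participants": s.n_participants})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_group_summaries(path: str | Path) -> list[GroupSummary]:
    # "n/a" is a legitimate feedback level, not a missing value
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    out = []
    for _, row in df.iterrows():
        cond = _condition_from_dict(row)
        out.append(GroupSummary(cond, float(row["bias_m"]), float(row["se_m"]),
                                float(row["sd_m"]), int(row["n_participants"])))
    return out


def write_manifest(path: str | Path, config: RunConfig,
                   extras: dict | None = None) -> None:
    """Record everything needed to reproduce a run."""
    import fieldcenter

    payload = {"config": asdict(config),
               "fieldcenter_version": fieldcenter.__version__,
               "numpy_version": np.__version__}
    if extras:
        payload.update(extras)
    Path(path).write_text(json.dumps(payload, indent=1))
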