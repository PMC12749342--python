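"""YAML-backed run configuration.

One nested parameter tree covers every stage; unknown keys are rejected
(typos must fail loudly, not silently fall back to defaults), and every CLI
run echoes the fully-resolved tree next to its outputs so the echo is itself
a valid, reproducing input.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .errors import InputError
from .register import RefineOptions, RegistrationParams
from .segment import PreprocessParams
from .synthetic import DEFAULT_GT, DEFAULT_SCENE, RenderParams


def _defaults_tree() -> dict:
    return {
        "seed": 0,
        "verbosity": 1,
        "preprocess": dataclasses.asdict(PreprocessParams()),
        "segmentation": {"min_radius_nm": 150.0, "max_radius_nm": 1500.0,
                         "polarity": "auto"},
        "refine": dataclasses.asdict(RefineOptions()),
        "registration": {"warp_smoothing": 0.0, "do_warp": True,
                         "match_gate_nm": 2000.0},
        "scene": dict(DEFAULT_SCENE),
        "ground_truth": dict(DEFAULT_GT),
        "render": dataclasses.asdict(RenderParams()),
        "frc": {"ring_width_bins": 1, "window": "hann", "threshold": 0.25},
    }


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, val in override.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise InputError(f"unknown config key '{where}'")
        if isinstance(defaults[key], dict):
            if not isinstance(val, dict):
                raise InputError(f"config key '{where}' must be a mapping")
            out[key] = _merge(defaults[key], val, where)
        else:
            out[key] = val
    return out


@dataclass
class RunConfig:
    """Fully-resolved parameter tree for one run."""

    tree: dict = field(default_factory=_defaults_tree)

    @classmethod
    def load(cls, path: Optional[str] = None, overrides: Optional[dict] = None
             ) -> "RunConfig":
        tree = _defaults_tree()
        if path is not None:
            with open(path, "r", encoding="utf-8") as fh:
                user = yaml.safe_load(fh) or {}
            if not isinstance(user, dict):
                raise InputError(f"{path}: config root must be a mapping")
            tree = _merge(tree, user)
        if overrides:
            tree = _merge(tree, overrides)
        return cls(tree=tree)

    def dump(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.tree, fh, sort_keys=False)

    # -- typed accessors ---------------------------------------------------
    @property
    def seed(self) -> int:
        return int(self.tree["seed"])

    def preprocess_params(self) -> PreprocessParams:
        return PreprocessParams(**self.tree["preprocess"])

    def refine_options(self) -> RefineOptions:
        d = dict(self.tree["refine"])
        d["scale_bounds"] = tuple(d["scale_bounds"])
        return RefineOptions(**d)

    def registration_params(self) -> RegistrationParams:
        seg = self.tree["segmentation"]
        reg = self.tree["registration"]
        return RegistrationParams(
            preprocess=self.preprocess_params(),
            min_radius_nm=seg["min_radius_nm"],
            max_radius_nm=seg["max_radius_nm"],
            refine=self.refine_options(),
            warp_smoothing=reg["warp_smoothing"],
            do_warp=reg["do_warp"],
            match_gate_nm=reg["match_gate_nm"],
        )

    def render_params(self, seed: Optional[int] = None) -> RenderParams:
        d = dict(self.tree["render"])
        if seed is not None:
            d["seed"] = seed
        return RenderParams(**d)
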