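"""Declarative pipeline configuration: YAML schema, validation, defaults.

Validation is exhaustive — every type/range violation in the file is
reported, not just the first — and normalisation is idempotent: the
defaults are injected once and re-normalising a normalised config is the
identity.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .io import ValidationError

SAMPLE_ROLES = ("control_untreated", "control_solvent", "treated_line", "em3_line")

#: defaults of the DMR definition and downstream analyses
DEFAULTS = {
    "seed": 0,
    "genome_id": "genome",
    "output_dir": "dmrkit_out",
    "params": {
        "bin_size": 100,
        "merge_gap": 200,
        "min_cov": 4,
        "CG": {"min_dmc": 4, "min_diff": 0.40},
        "CHG": {"min_dmc": 5, "min_diff": 0.35},
        "ectopic_CHG": {"min_dmc": 3, "min_diff": 0.15, "control_max_level": 0.02},
    },
    "window": 1000,
    "restore_threshold": 0.8,
    "min_loss": 0.2,
    "simulate": None,
    "samples": [],
    "annotation": None,
    "deg_lists": [],
}

_TOP_KEYS = set(DEFAULTS)
_PARAM_KEYS = {"bin_size", "merge_gap", "min_cov", "CG", "CHG", "ectopic_CHG"}
_CONTEXT_PARAM_KEYS = {"min_dmc", "min_diff", "control_max_level"}
_SAMPLE_KEYS = {"id", "role", "path", "replicate_group"}

_RANGES = {
    "min_diff": (0.0, 1.0, "exclusive-min"),
    "control_max_level": (0.0, 1.0, "inclusive"),
    "restore_threshold": (0.0, 1.0, "inclusive"),
    "min_loss": (0.0, 1.0, "inclusive"),
}


class ConfigError(ValidationError):
    """Carries the full list of validation problems."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid config:\n  " + "\n  ".join(problems))


def _check_range(key: str, value, problems: list[str], prefix: str = "") -> None:
    lo, hi, kind = _RANGES[key]
    label = f"{prefix}{key}"
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        problems.append(f"{label}: expected a number, got {value!r}")
        return
    if kind == "exclusive-min":
        if not (lo < value <= hi):
            problems.append(f"{label}: must be in ({lo}, {hi}], got {value}")
    elif not (lo <= value <= hi):
        problems.append(f"{label}: must be in [{lo}, {hi}], got {value}")


def normalize_config(raw: dict) -> dict:
    """Inject defaults and validate; raises ConfigError listing every problem."""
    problems: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(["config root must be a mapping"])
    unknown = set(raw) - _TOP_KEYS
    for key in sorted(unknown):
        problems.append(f"unknown key {key!r}")
    cfg = copy.deepcopy(DEFAULTS)
    for key in _TOP_KEYS & set(raw):
        if key == "params" and isinstance(raw[key], dict):
            for pk, pv in raw[key].items():
                if pk not in _PARAM_KEYS:
                    problems.append(f"params: unknown key {pk!r}")
                elif pk in ("CG", "CHG", "ectopic_CHG"):
                    if not isinstance(pv, dict):
                        problems.append(f"params.{pk}: expected a mapping")
                        continue
                    for ck, cv in pv.items():
                        if ck not in _CONTEXT_PARAM_KEYS:
                            problems.append(f"params.{pk}: unknown key {ck!r}")
                        else:
                            cfg["params"][pk][ck] = cv
                else:
                    cfg["params"][pk] = pv
        else:
            cfg[key] = copy.deepcopy(raw[key])

    for ctx in ("CG", "CHG", "ectopic_CHG"):
        sub = cfg["params"][ctx]
        if "min_diff" in sub:
            _check_range("min_diff", sub["min_diff"], problems, prefix=f"params.{ctx}.")
        md = sub.get("min_dmc")
        if not isinstance(md, int) or md < 1:
            problems.append(f"params.{ctx}.min_dmc: must be an integer >= 1, got {md!r}")
    for key in ("bin_size", "merge_gap", "min_cov"):
        v = cfg["params"][key]
        if not isinstance(v, int) or v < 0 or (key == "bin_size" and v < 1):
            problems.append(f"params.{key}: must be a non-negative integer, got {v!r}")
    for key in ("restore_threshold", "min_loss"):
        _check_range(key, cfg[key], problems)
    if not isinstance(cfg["window"], int) or cfg["window"] < 0:
        problems.append(f"window: must be an integer >= 0, got {cfg['window']!r}")
    if not isinstance(cfg["seed"], int):
        problems.append(f"seed: must be an integer, got {cfg['seed']!r}")

    samples = cfg["samples"] or []
    if not isinstance(samples, list):
        problems.append("samples: expected a list")
        samples = []
    ids = set()
    for i, s in enumerate(samples):
        if not isinstance(s, dict):
            problems.append(f"samples[{i}]: expected a mapping")
            continue
        for k in set(s) - _SAMPLE_KEYS:
            problems.append(f"samples[{i}]: unknown key {k!r}")
        if s.get("role") not in SAMPLE_ROLES:
            problems.append(f"samples[{i}].role: must be one of {SAMPLE_ROLES}, got {s.get('role')!r}")
        sid = s.get("id")
        if not sid:
            problems.append(f"samples[{i}].id: required")
        elif sid in ids:
            problems.append(f"samples[{i}].id: duplicate id {sid!r}")
        else:
            ids.add(sid)
        if cfg["simulate"] is None and not s.get("path"):
            problems.append(f"samples[{i}].path: required when not simulating")
    if cfg["simulate"] is None and samples:
        roles = {s.get("role") for s in samples if isinstance(s, dict)}
        if not roles & {"control_untreated", "control_solvent"}:
            problems.append("samples: need at least one control sample")
        if "treated_line" not in roles:
            problems.append("samples: need at least one treated_line sample")
    if cfg["simulate"] is None and not samples:
        problems.append("either 'simulate' or 'samples' must be provided")
    if cfg["simulate"] is not None and not isinstance(cfg["simulate"], dict):
        problems.append("simulate: expected a mapping of simulator options")

    if problems:
        raise ConfigError(problems)
    return cfg


def validate_config(path: str | Path) -> dict:
    """Load a YAML config file and return the normalised config dict."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return normalize_config(raw)
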