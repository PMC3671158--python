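"""YAML configuration: the assay-design-like settings of a run/batch.

One document drives the whole pipeline: run metadata (isotype, conjugate,
reagent lot, ...), normalization choices, curve-fit weighting, flag
thresholds, positivity baselines/thresholds, and — for the synthetic
generator — the simulated assay itself.  Unknown keys warn rather than
fail so a shared config can carry lab-specific extras.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import yaml

from .analysis import AnalysisOptions
from .curves import LogisticParams
from .errors import ConfigError
from .models import RunMetadata
from .normalization import NormalizationOptions
from .qc_within import FlagThresholds, PositivityParams
from .synthetic import (
    AnalyteSpec,
    SynthConfig,
    TitrationSpec,
    UnknownSpec,
    default_config,
)

__all__ = [
    "load_config",
    "analysis_options_from_config",
    "run_metadata_from_config",
    "synth_config_from_config",
]

_KNOWN_TOP = {"run", "analysis", "positivity", "generate"}
_KNOWN_RUN = {
    "run_name", "isotype", "conjugate", "performer", "reagent_lot",
    "batch_id",
}
_KNOWN_ANALYSIS = {
    "subtract_background", "subtract_blank_bead", "blank_bead_analyte",
    "log_transform", "weight_exponent", "cv_basis", "interpolation_model",
    "fi_gate", "cv_limit_unknown", "cv_limit_titration", "seed",
}
_KNOWN_GENERATE = {
    "seed", "noise_cv", "n_replicates", "blank_bead", "include_summary",
    "background_fi_mean", "standard", "qc", "analytes", "unknowns",
    "run_name",
}


def load_config(path: Path | str | None) -> dict:
    if path is None:
        return {}
    try:
        doc = yaml.safe_load(Path(path).read_text()) or {}
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}") from None
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    _warn_unknown(doc, _KNOWN_TOP, "top level")
    _warn_unknown(doc.get("run", {}), _KNOWN_RUN, "run")
    _warn_unknown(doc.get("analysis", {}), _KNOWN_ANALYSIS, "analysis")
    _warn_unknown(doc.get("generate", {}), _KNOWN_GENERATE, "generate")
    return doc


def _warn_unknown(section: dict, known: set[str], where: str) -> None:
    if not isinstance(section, dict):
        raise ConfigError(f"config section {where!r} must be a mapping")
    for key in section:
        if key not in known:
            warnings.warn(
                f"unknown config key {key!r} in {where} section (ignored)",
                stacklevel=3,
            )


def run_metadata_from_config(doc: dict, default_name: str) -> RunMetadata:
    run = doc.get("run", {})
    return RunMetadata(
        run_name=run.get("run_name", default_name),
        isotype=run.get("isotype", ""),
        conjugate=run.get("conjugate", ""),
        performer=run.get("performer", ""),
        reagent_lot=run.get("reagent_lot", ""),
        batch_id=run.get("batch_id", ""),
    )


def analysis_options_from_config(doc: dict) -> AnalysisOptions:
    a = doc.get("analysis", {})
    if a.get("subtract_blank_bead") and not a.get("blank_bead_analyte"):
        raise ConfigError(
            "config key 'analysis.blank_bead_analyte' is required when "
            "'analysis.subtract_blank_bead' is enabled"
        )
    norm = NormalizationOptions(
        subtract_blank_bead=bool(a.get("subtract_blank_bead", False)),
        subtract_background=bool(a.get("subtract_background", False)),
        log_transform=bool(a.get("log_transform", False)),
        blank_bead_analyte=a.get("blank_bead_analyte"),
    )
    thresholds = FlagThresholds(
        fi_gate=float(a.get("fi_gate", 100.0)),
        cv_limit_unknown=float(a.get("cv_limit_unknown", 15.0)),
        cv_limit_titration=float(a.get("cv_limit_titration", 20.0)),
    )
    return AnalysisOptions(
        normalization=norm,
        weight_exponent=float(a.get("weight_exponent", 1.8)),
        thresholds=thresholds,
        cv_basis=a.get("cv_basis", "subtracted"),
        interpolation_model=a.get("interpolation_model", "fivepl"),
        positivity=_positivity_from_config(doc),
        seed=int(a.get("seed", 0)),
    )


def _positivity_from_config(
    doc: dict,
) -> dict[tuple[str, str], PositivityParams]:
    section = doc.get("positivity")
    if not section:
        return {}
    fold = float(section.get("fold_change", 3.0))
    thresholds = {
        analyte: float(spec.get("threshold", 0.0))
        for analyte, spec in (section.get("analytes") or {}).items()
    }
    out: dict[tuple[str, str], PositivityParams] = {}
    for item in section.get("baselines") or []:
        analyte = item["analyte"]
        if analyte not in thresholds:
            warnings.warn(
                f"positivity baseline for analyte {analyte!r} has no "
                "matching threshold; call will be skipped",
                stacklevel=3,
            )
            continue
        out[(item["description"], analyte)] = PositivityParams(
            baseline=float(item["baseline"]),
            threshold=thresholds[analyte],
            fold_change=fold,
        )
    return out


def synth_config_from_config(doc: dict, seed: int | None) -> SynthConfig:
    """Build the generator configuration; the study-condition defaults
    apply wherever the config is silent."""
    g = doc.get("generate", {})
    if seed is None:
        seed = int(g.get("seed", 0))
    overrides = {}
    for key in ("noise_cv", "background_fi_mean"):
        if key in g:
            overrides[key] = float(g[key])
    for key in ("blank_bead", "include_summary"):
        if key in g:
            overrides[key] = bool(g[key])
    if "n_replicates" in g:
        overrides["n_replicates"] = int(g["n_replicates"])
    if "run_name" in g:
        overrides["run_name"] = str(g["run_name"])
    cfg = default_config(seed=seed, **overrides)
    if "standard" in g:
        cfg.standard = _titration_from(g["standard"])
    if "qc" in g:
        cfg.qc = _titration_from(g["qc"])
    if "analytes" in g:
        cfg.analytes = [
            AnalyteSpec(
                name=item["name"],
                bead_number=int(item.get("bead_number", i + 1)),
                params=LogisticParams(
                    a_min=float(item.get("a_min", 50.0)),
                    a_max=float(item.get("a_max", 30000.0)),
                    m=float(item.get("m", 500.0)),
                    h=float(item.get("h", 1.0)),
                    s=float(item.get("s", 1.0)),
                ),
                unit=item.get("unit", "pg/ml"),
            )
            for i, item in enumerate(g["analytes"])
        ]
    if "unknowns" in g:
        cfg.unknowns = [
            UnknownSpec(
                id=item["id"],
                true_conc=float(item["true_conc"]),
                dilution=float(item.get("dilution", 100.0)),
            )
            for item in g["unknowns"]
        ]
    cfg.validate()
    return cfg


def _titration_from(section: dict) -> TitrationSpec:
    spec = TitrationSpec()
    if "top_conc" in section:
        spec.top_conc = float(section["top_conc"])
    if "dilutions" in section:
        spec.dilutions = [float(d) for d in section["dilutions"]]
    return spec
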