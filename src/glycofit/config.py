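"""Run configuration: validated settings for a batch pipeline run."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .isotherm import ClassificationRules, IsothermError

__all__ = ["PlotToggles", "RunConfig", "ConfigError", "validate_config"]


class ConfigError(ValueError):
    pass


@dataclass
class PlotToggles:
    curves: bool = True
    bars: bool = True
    heatmap: bool = True
    ka_vs_rfu: bool = True
    rank_table: bool = True
    rings: bool = True

    @classmethod
    def none(cls) -> "PlotToggles":
        return cls(False, False, False, False, False, False)


@dataclass
class RunConfig:
    """Fully resolved settings of one pipeline run.

    ``files`` maps GPR paths (resolved against ``input_dir``) to protein
    concentrations in µM.  Classification thresholds live in ``rules``;
    see :class:`glycofit.isotherm.ClassificationRules` for meanings and
    defaults.
    """

    input_dir: Path
    files: dict[Path, float]
    output_dir: Path
    catalog: Path | None = None
    truth: Path | None = None
    protein: str = ""
    channel: int | None = None
    replicate_policy: str = "mean_all"
    exclude_flagged: bool = True
    clamp_negative: bool = True
    on_missing: str = "error"
    rules: ClassificationRules = field(default_factory=ClassificationRules)
    plots: PlotToggles = field(default_factory=PlotToggles)
    top_n: int = 60
    sort_by: str = "rfu"
    seed: int = 0

    def echo(self) -> dict:
        """JSON-serialisable view of the resolved configuration."""
        d = asdict(self)
        d["input_dir"] = str(self.input_dir)
        d["output_dir"] = str(self.output_dir)
        d["catalog"] = str(self.catalog) if self.catalog else None
        d["truth"] = str(self.truth) if self.truth else None
        d["files"] = {str(p): c for p, c in self.files.items()}
        return d


_KNOWN_KEYS = {
    "input_dir", "files", "output_dir", "catalog", "truth", "protein",
    "channel", "replicate_policy", "exclude_flagged", "clamp_negative",
    "on_missing", "thresholds", "plots", "top_n", "sort_by", "seed",
}

_THRESHOLD_KEYS = {
    "occupancy_threshold", "kd_rel_se_max", "binder_floor_rfu", "binder_floor_k_sd",
}


def _parse_files(raw, base: Path) -> dict[Path, float]:
    """Accept either a mapping {file: conc} or a list of
    {file:, concentration:} entries (the list form can express — and we
    reject — duplicate files, which a YAML mapping would silently merge)."""
    entries: list[tuple[str, object]] = []
    if isinstance(raw, dict):
        entries = list(raw.items())
    elif isinstance(raw, list):
        for item in raw:
            if not isinstance(item, dict) or "file" not in item or "concentration" not in item:
                raise ConfigError(
                    f"files: each list entry needs 'file' and 'concentration', got {item!r}"
                )
            entries.append((item["file"], item["concentration"]))
    else:
        raise ConfigError("files: must be a mapping or a list of entries")

    out: dict[Path, float] = {}
    for name, conc in entries:
        try:
            c = float(conc)
        except (TypeError, ValueError):
            raise ConfigError(f"files[{name!r}]: concentration {conc!r} is not numeric")
        if c <= 0:
            raise ConfigError(
                f"files[{name!r}]: concentration must be positive µM, got {c}"
            )
        path = (base / name).resolve() if not Path(name).is_absolute() else Path(name)
        if path in out:
            raise ConfigError(f"files: duplicate mapping for {name!r}")
        out[path] = c
    if len(out) < 2:
        raise ConfigError(
            "files: at least 2 concentrations are required for isotherm fits"
        )
    return out


def validate_config(path: str | Path, **overrides) -> RunConfig:
    """Load and validate a YAML run config; returns the resolved RunConfig.

    Every error names the offending field.  ``overrides`` replace
    top-level keys before validation (the CLI flags use this).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    raw.update({k: v for k, v in overrides.items() if v is not None})

    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")

    base = Path(raw.get("input_dir") or path.parent)
    if not base.is_absolute():
        base = (path.parent / base).resolve()
    if not base.is_dir():
        raise ConfigError(f"input_dir: directory does not exist: {base}")

    if "files" not in raw:
        raise ConfigError("files: required key is missing")
    files = _parse_files(raw["files"], base)
    for p in files:
        if not p.exists():
            raise ConfigError(f"files: {p} does not exist")

    catalog = raw.get("catalog")
    if catalog is not None:
        catalog = (base / catalog) if not Path(catalog).is_absolute() else Path(catalog)
        if not catalog.exists():
            raise ConfigError(f"catalog: {catalog} does not exist")
    truth = raw.get("truth")
    if truth is not None:
        truth = (base / truth) if not Path(truth).is_absolute() else Path(truth)
        if not truth.exists():
            raise ConfigError(f"truth: {truth} does not exist")

    thresholds = raw.get("thresholds") or {}
    bad = set(thresholds) - _THRESHOLD_KEYS
    if bad:
        raise ConfigError(f"thresholds: unknown key(s) {sorted(bad)}")
    try:
        rules = ClassificationRules(**thresholds)
    except IsothermError as e:
        raise ConfigError(f"thresholds: {e}") from e

    plots_raw = raw.get("plots")
    if plots_raw is None:
        plots = PlotToggles()
    elif plots_raw is False:
        plots = PlotToggles.none()
    elif isinstance(plots_raw, dict):
        bad = set(plots_raw) - set(PlotToggles().__dict__)
        if bad:
            raise ConfigError(f"plots: unknown toggle(s) {sorted(bad)}")
        plots = PlotToggles(**plots_raw)
    else:
        raise ConfigError("plots: must be a mapping of toggles or false")

    policy = raw.get("replicate_policy", "mean_all")
    if policy not in ("mean_all", "trimmed"):
        raise ConfigError(f"replicate_policy: must be mean_all or trimmed, got {policy!r}")
    on_missing = raw.get("on_missing", "error")
    if on_missing not in ("error", "drop"):
        raise ConfigError(f"on_missing: must be error or drop, got {on_missing!r}")
    sort_by = raw.get("sort_by", "rfu")
    if sort_by not in ("rfu", "ka"):
        raise ConfigError(f"sort_by: must be rfu or ka, got {sort_by!r}")
    top_n = int(raw.get("top_n", 60))
    if top_n < 1:
        raise ConfigError(f"top_n: must be >= 1, got {top_n}")

    output_dir = Path(raw.get("output_dir") or (path.parent / "glycofit-run"))

    return RunConfig(
        input_dir=base,
        files=files,
        output_dir=output_dir,
        catalog=catalog,
        truth=truth,
        protein=str(raw.get("protein", "")),
        channel=raw.get("channel"),
        replicate_policy=policy,
        exclude_flagged=bool(raw.get("exclude_flagged", True)),
        clamp_negative=bool(raw.get("clamp_negative", True)),
        on_missing=on_missing,
        rules=rules,
        plots=plots,
        top_n=top_n,
        sort_by=sort_by,
        seed=int(raw.get("seed", 0)),
    )
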