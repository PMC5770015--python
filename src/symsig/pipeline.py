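"""Reproducible generate → measure → model → report pipeline.

A run takes a :class:`PipelineConfig` (YAML or dict), executes the requested
stages in dependency order into a run directory, and writes a manifest of
SHA-256 checksums.  Reruns with the same config and seed reproduce identical
checksums, bootstrap CIs included.

Stages
------
generate : synthesise a study (schedule.csv, signals.csv, tags.csv, jd.csv,
           responses.csv, ratings.csv, truth.json, images/)
measure  : recompute perimetric complexity from the images and JD_mu from
           tags.csv into complexity.csv and jd.csv (in real-data mode these
           are the first computations; in synthetic mode they cross-check
           the generator's own measurements)
model    : fit the thirteen-model mixed-effects suite -> models.json
report   : report.md summary table plus trend plots
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .complexity import binarise, perimetric_complexity
from .errors import ConfigurationError, DataIntegrityError, SymsigError
from .generate import StudyConfig, generate_study, jd_table
from .ground import tagger_agreement
from .models import run_model_suite

logger = logging.getLogger(__name__)

_STAGES = ("generate", "measure", "model", "report")

_KNOWN_KEYS = {
    "seed", "out_dir", "stages", "real_data_dir", "study", "pc_threshold",
    "bootstrap_reps", "write_images",
}


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration (unknown keys are rejected)."""

    seed: int = 0
    out_dir: str = "runs/run0"
    stages: tuple[str, ...] = _STAGES
    real_data_dir: str | None = None
    study: StudyConfig = field(default_factory=StudyConfig)
    pc_threshold: str | float = "automatic"  # "automatic" or a fixed intensity
    bootstrap_reps: int = 200
    write_images: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "study" in d and isinstance(d["study"], dict):
            d["study"] = StudyConfig.from_dict(d["study"])
        if "stages" in d:
            bad = set(d["stages"]) - set(_STAGES)
            if bad:
                raise ConfigurationError(f"unknown stages: {sorted(bad)}")
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "out_dir": str(self.out_dir),
            "stages": list(self.stages),
            "real_data_dir": self.real_data_dir,
            "study": self.study.to_dict(),
            "pc_threshold": self.pc_threshold,
            "bootstrap_reps": self.bootstrap_reps,
            "write_images": self.write_images,
        }


def run_pipeline(config: PipelineConfig, force: bool = False) -> Path:
    """Run the requested stages; returns the run directory.

    The fully resolved config is written next to the outputs, and
    manifest.json lists a SHA-256 checksum per produced file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))

    data_dir = Path(config.real_data_dir) if config.real_data_dir else out
    for stage in _STAGES:
        if stage not in config.stages:
            continue
        if stage == "generate":
            if config.real_data_dir:
                raise ConfigurationError("stage 'generate' conflicts with real_data_dir")
            generate_study(config.study, config.seed, out, force=True,
                           write_images=config.write_images)
        elif stage == "measure":
            _stage_measure(config, data_dir, out)
        elif stage == "model":
            _stage_model(config, data_dir, out)
        elif stage == "report":
            _stage_report(out)

    manifest = {
        p.relative_to(out).as_posix(): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise ConfigurationError(
            f"missing upstream artefact {path.name}: run stage {producer!r} first "
            "or point real_data_dir at existing data"
        )
    return path


def _stage_measure(config: PipelineConfig, data_dir: Path, out: Path) -> None:
    """Perimetric complexity from images; JD_mu from tag sets."""
    signals = pd.read_csv(_require(data_dir / "signals.csv", "generate"))
    rows = []
    if "image_path" in signals.columns and signals["image_path"].notna().any():
        from PIL import Image

        for r in signals.itertuples():
            img = np.asarray(Image.open(data_dir / r.image_path).convert("L"))
            if config.pc_threshold == "automatic":
                mask = binarise(img, method="automatic")
            else:
                mask = binarise(img, method="fixed", threshold=float(config.pc_threshold))
            c = perimetric_complexity(mask)
            rows.append(
                {
                    "signal_id": r.signal_id,
                    "ink": c.ink,
                    "perimeter_inside": c.perimeter_inside,
                    "perimeter_outside": c.perimeter_outside,
                    "pc": c.pc,
                    "log_pc": c.log_pc,
                }
            )
    else:  # no images on disk: carry the generator's in-memory measurements
        for r in signals.itertuples():
            rows.append(
                {
                    "signal_id": r.signal_id,
                    "ink": r.ink if hasattr(r, "ink") else np.nan,
                    "perimeter_inside": np.nan,
                    "perimeter_outside": np.nan,
                    "pc": r.pc if hasattr(r, "pc") else np.nan,
                    "log_pc": r.log_pc,
                }
            )
    pd.DataFrame(rows).to_csv(out / "complexity.csv", index=False, float_format="%.10g")

    tags = pd.read_csv(_require(data_dir / "tags.csv", "generate"), keep_default_na=False)
    jd_table(tags).to_csv(out / "jd.csv", index=False, float_format="%.10g")


def load_analysis_table(data_dir: Path) -> pd.DataFrame:
    """Join signals, complexity, responses, ratings and JD into one table."""
    signals = pd.read_csv(_require(data_dir / "signals.csv", "generate"))
    comp = pd.read_csv(_require(data_dir / "complexity.csv", "measure"))
    resp = pd.read_csv(_require(data_dir / "responses.csv", "generate"))
    ratings = pd.read_csv(_require(data_dir / "ratings.csv", "generate"))
    jd = pd.read_csv(_require(data_dir / "jd.csv", "measure"))

    df = signals.drop(columns=[c for c in ("ink", "pc", "log_pc") if c in signals.columns])
    df = df.merge(comp[["signal_id", "pc", "log_pc"]], on="signal_id", how="left")
    df = df.merge(resp[["signal_id", "receiver_id", "accuracy", "insight"]],
                  on="signal_id", how="left")
    df = df.merge(ratings[["signal_id", "iconicity", "familiarity"]], on="signal_id", how="left")
    cons = jd[jd.tagger == "consensus"].set_index("item")["jd_mu"]
    df["jd_mu"] = df["item"].map(cons)
    return df


def _stage_model(config: PipelineConfig, data_dir: Path, out: Path) -> None:
    # complexity.csv/jd.csv are written into the run dir by 'measure'
    measure_dir = out if (out / "complexity.csv").exists() else data_dir
    table_dir = _MergedDirs(data_dir, measure_dir)
    df = load_analysis_table(table_dir)
    suite = run_model_suite(df, bootstrap_reps=config.bootstrap_reps, seed=config.seed)
    (out / "models.json").write_text(json.dumps(suite.to_records(), indent=2, sort_keys=True))


class _MergedDirs:
    """Path-like view preferring the run dir over the input dir per file."""

    def __init__(self, data_dir: Path, measure_dir: Path):
        self.data_dir = Path(data_dir)
        self.measure_dir = Path(measure_dir)

    def __truediv__(self, name: str) -> Path:
        cand = self.measure_dir / name
        return cand if cand.exists() else self.data_dir / name


def _stage_report(out: Path) -> None:
    models_path = _require(out / "models.json", "model")
    records = json.loads(models_path.read_text())
    lines = [
        "# Model suite report",
        "",
        "| analysis | family | n | term | beta | SE | stat | p | 95% CI | structure |",
        "|---|---|---|---|---|---|---|---|---|---|",
    ]
    for rec in records:
        for c in rec["coefficients"]:
            ci = (
                f"[{c['ci_lower']:.3f}, {c['ci_upper']:.3f}]"
                if c["ci_lower"] is not None
                else "-"
            )
            lines.append(
                f"| {rec['analysis_id']} | {rec['family']} | {rec['n_obs']} | {c['term']} "
                f"| {c['beta']:.3f} | {c['se']:.3f} | {c['stat']:.2f} | {c['p']:.3g} "
                f"| {ci} | {rec['structure_used']} |"
            )
    (out / "report.md").write_text("\n".join(lines) + "\n")
    _trend_plots(out)


def _trend_plots(out: Path) -> None:
    try:
        df = load_analysis_table(_MergedDirs(out, out))
    except (ConfigurationError, FileNotFoundError):
        return
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
    df.groupby("turn")["pc"].mean().plot(ax=axes[0], marker="o", title="mean PC vs turn")
    df.groupby("time_seen")["insight"].mean().plot(
        ax=axes[1], marker="o", title="mean insight vs time seen"
    )
    df.groupby("turn")["accuracy"].mean().plot(ax=axes[2], marker="o", title="accuracy vs turn")
    fig.tight_layout()
    fig.savefig(out / "trends.png", dpi=100)
    plt.close(fig)


# --------------------------------------------------------------------------- #
# validation of (real-data) inputs
# --------------------------------------------------------------------------- #

_COLUMN_CONTRACTS = {
    "schedule.csv": ["pair_id", "round", "turn", "position", "item", "signaller_id", "receiver_id"],
    "signals.csv": ["signal_id", "pair_id", "round", "turn", "item", "signaller_id",
                    "is_first_exposure", "time_seen"],
    "tags.csv": ["signal_id", "item", "tagger_id", "tags"],
    "responses.csv": ["signal_id", "pair_id", "receiver_id", "item", "guess",
                      "accuracy", "insight"],
    "ratings.csv": ["signal_id", "item", "iconicity", "familiarity"],
}


def validate_inputs(data_dir: str | Path) -> list[str]:
    """Check column contracts, referential integrity, rating ranges and image
    readability; returns a list of human-readable violations (empty = valid)."""
    data_dir = Path(data_dir)
    violations: list[str] = []
    tables: dict[str, pd.DataFrame] = {}
    for fname, cols in _COLUMN_CONTRACTS.items():
        path = data_dir / fname
        if not path.exists():
            violations.append(f"{fname}: file missing")
            continue
        df = pd.read_csv(path, keep_default_na=fname != "tags.csv")
        tables[fname] = df
        missing = [c for c in cols if c not in df.columns]
        if missing:
            violations.append(f"{fname}: missing columns {missing}")

    sig = tables.get("signals.csv")
    if sig is not None and "signal_id" in sig.columns:
        known = set(sig.signal_id)
        for fname in ("tags.csv", "responses.csv", "ratings.csv"):
            df = tables.get(fname)
            if df is not None and "signal_id" in df.columns:
                dangling = sorted(set(df.signal_id) - known)
                for d in dangling[:20]:
                    violations.append(f"{fname}: signal_id {d!r} not present in signals.csv")
        if "image_path" in sig.columns:
            from PIL import Image, UnidentifiedImageError

            for r in sig.itertuples():
                if not isinstance(r.image_path, str):
                    continue
                p = data_dir / r.image_path
                if not p.exists():
                    violations.append(f"signals.csv: image {r.image_path} missing")
                    continue
                try:
                    Image.open(p).verify()
                except (UnidentifiedImageError, OSError):
                    violations.append(f"signals.csv: image {r.image_path} unreadable")

    resp = tables.get("responses.csv")
    if resp is not None:
        if "insight" in resp.columns:
            bad = resp[~resp.insight.isin(range(1, 8))]
            for r in bad.itertuples():
                violations.append(
                    f"responses.csv: insight rating {r.insight} out of 1..7 for {r.signal_id}"
                )
        if "accuracy" in resp.columns:
            bad = resp[~resp.accuracy.isin([0, 1])]
            for r in bad.itertuples():
                violations.append(f"responses.csv: accuracy {r.accuracy} not 0/1 for {r.signal_id}")

    ratings = tables.get("ratings.csv")
    if ratings is not None:
        for col in ("iconicity", "familiarity"):
            if col in ratings.columns:
                vals = ratings[col].dropna()
                bad = ratings.loc[vals[(vals < 1) | (vals > 7)].index]
                for r in bad.itertuples():
                    violations.append(
                        f"ratings.csv: {col} {getattr(r, col)} out of 1..7 for {r.signal_id}"
                    )
    return violations


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
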