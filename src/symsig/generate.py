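"""Synthetic study generator with known ground-truth parameters.

The generator emulates the full study: pairs play seeded 8-round games over
a 25-item pool (10-item shortlists, one replacement before rounds 3/5/7);
each drawing event samples or evolves a *ground* (a tag set) from a
per-item salience model; drawings are rendered from the tags; two simulated
taggers recode the first-exposure drawings; and receiver behaviour (guess
accuracy, 1-7 insight ratings) plus crowd ratings (iconicity, familiarity)
are generated from a regression-style behaviour model whose coefficient
signs mirror the phenomena of interest: insight falls with the time an item
has been seen and with signal familiarity, rises with the item's ground
unpredictability (JD_mu) on first exposure; accuracy rises as signals grow
familiar and simpler.

All parameters are recorded in ``truth`` for recovery tests, and everything
is deterministic under a fixed seed, including image bytes.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .complexity import perimetric_complexity
from .errors import ConfigurationError, DataIntegrityError
from .game import (
    GameSchedule,
    ScheduleConfig,
    build_schedule,
    link_familiarity_chain,
    signal_records,
)
from .glyphs import GlyphLibrary, render_signal
from .ground import ItemJD, TagSet, consensus_jd, item_jd_mean, jaccard_distance
from .items import DEFAULT_ITEMS

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------- #
# generating models
# --------------------------------------------------------------------------- #


@dataclass
class GroundModel:
    """Per-item tag-salience model.

    Each item has a private vocabulary of ``vocab_size`` candidate elements
    with base salience scores s.  Inclusion probabilities are

        p = clip(lam * softmax(theta_i * s), 0, 1)

    where ``lam`` sets the expected number of tags in a fresh signal and the
    concentration ``theta_i = theta * exp(eps_i)`` controls predictability:
    high theta piles mass on few always-drawn elements (low expected pairwise
    JD), low theta spreads it (high JD).  ``theta_log_spread`` is the SD of
    the per-item log-concentration jitter eps, giving items a range of
    ground unpredictability.
    """

    items: tuple[str, ...]
    vocab_size: int = 12
    lam: float = 4.0
    theta: float = 2.0
    theta_log_spread: float = 0.8
    salience: dict[str, list[float]] = field(default_factory=dict)
    item_theta: dict[str, float] = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        items: tuple[str, ...] = DEFAULT_ITEMS,
        seed: int | np.random.Generator = 0,
        vocab_size: int = 12,
        lam: float = 4.0,
        theta: float = 2.0,
        theta_log_spread: float = 0.8,
    ) -> "GroundModel":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        salience = {it: [float(v) for v in rng.normal(size=vocab_size)] for it in items}
        item_theta = {
            it: float(theta * np.exp(rng.normal(scale=theta_log_spread))) for it in items
        }
        return cls(
            items=tuple(items),
            vocab_size=vocab_size,
            lam=lam,
            theta=theta,
            theta_log_spread=theta_log_spread,
            salience=salience,
            item_theta=item_theta,
        )

    def vocab(self, item: str) -> list[str]:
        stem = item.upper().replace(" ", "_")
        return [f"{stem}:E{j}" for j in range(self.vocab_size)]

    def inclusion_probs(self, item: str) -> np.ndarray:
        s = np.asarray(self.salience[item])
        z = self.item_theta[item] * s
        w = np.exp(z - z.max())
        return np.clip(self.lam * w / w.sum(), 0.0, 1.0)

    def expected_jd(self, item: str, rng: np.random.Generator, n_pairs: int = 400) -> float:
        """Monte-Carlo expected pairwise JD of two fresh, independent grounds."""
        d = [
            jaccard_distance(
                sample_ground(item, self, rng), sample_ground(item, self, rng)
            )
            for _ in range(n_pairs)
        ]
        return float(np.mean(d))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundModel":
        d = dict(d)
        d["items"] = tuple(d["items"])
        return cls(**d)


@dataclass
class BehaviourModel:
    """Receiver/rater behaviour: directions encode the phenomena, magnitudes
    are conventions chosen for comfortable power at 20 pairs.

    Insight (latent gaussian, rounded and clamped to 1..7):
        b0 + b_jd * JD_mu * [first exposure] - b_fam * fam - b_time * (time_seen - 1)
    Accuracy (Bernoulli on the log-odds scale):
        g0 + g_jd * JD_mu + g_fam * fam + g_pc * (log_pc - pc_ref)
    with fam the Jaccard similarity of the signal to its chain predecessor
    (0 on first exposure).  Iconicity and familiarity ratings are clamped
    noisy transforms; their rating noise is divided by sqrt(n_raters) to
    emulate averaging over independent raters.
    """

    b0: float = 4.0
    b_jd: float = 2.5
    b_fam: float = 1.0
    b_time: float = 0.5
    sigma_insight: float = 1.0
    g0: float = 0.2
    g_jd: float = -2.0
    g_fam: float = 1.0
    g_pc: float = -0.6
    pc_ref: float = 4.5
    icon0: float = 5.5
    icon_jd: float = 2.0
    icon_time: float = 0.6
    sigma_iconicity: float = 1.0
    sigma_familiarity: float = 1.0
    n_raters: int = 10
    rho_reuse: float = 0.85
    delta_drop: float = 0.25

    def __post_init__(self) -> None:
        for name in ("rho_reuse", "delta_drop"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a probability, got {v}")
        for name in ("sigma_insight", "sigma_iconicity", "sigma_familiarity"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.b_jd < 0 or self.b_fam < 0 or self.b_time < 0:
            raise ConfigurationError("insight coefficients b_jd, b_fam, b_time must be >= 0")
        if self.g_jd > 0 or self.g_pc > 0 or self.g_fam < 0:
            raise ConfigurationError("accuracy signs: g_jd <= 0, g_pc <= 0, g_fam >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BehaviourModel":
        return cls(**d)


@dataclass(frozen=True)
class TaggerProfile:
    """A simulated coder: per-tag detection probability plus a private,
    bijective relabelling of the tag vocabulary (internal consistency)."""

    tagger_id: str
    detection: float
    relabel: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.relabel.values())) != len(self.relabel):
            raise ConfigurationError(f"tagger {self.tagger_id}: relabel map is not bijective")

    @classmethod
    def build(
        cls, tagger_id: str, ground: GroundModel, rng: np.random.Generator, detection: float = 0.9
    ) -> "TaggerProfile":
        universe = [t for it in ground.items for t in ground.vocab(it)]
        codes = rng.permutation(len(universe))
        relabel = {t: f"{tagger_id.upper()}_C{codes[i]}" for i, t in enumerate(universe)}
        return cls(tagger_id=tagger_id, detection=detection, relabel=relabel)


# --------------------------------------------------------------------------- #
# elementary sampling operations
# --------------------------------------------------------------------------- #


def sample_ground(item: str, ground: GroundModel, rng: np.random.Generator) -> frozenset[str]:
    """Draw a fresh ground: each vocabulary element independently with its
    inclusion probability, resampling until non-empty."""
    p = ground.inclusion_probs(item)
    vocab = ground.vocab(item)
    while True:
        mask = rng.random(len(p)) < p
        if mask.any():
            return frozenset(v for v, m in zip(vocab, mask) if m)


def evolve_signal(
    prev: frozenset[str],
    item: str,
    behaviour: BehaviourModel,
    ground: GroundModel,
    rng: np.random.Generator,
    level: int = 0,
) -> tuple[frozenset[str], bool]:
    """One production step: reuse-and-simplify the previous construal with
    probability ``rho_reuse``, otherwise re-construe from scratch.

    On the reuse branch each tag is independently dropped with probability
    ``delta_drop / (1 + level)`` (at least one tag kept): simplification is
    front-loaded, so a repeatedly reused signal converges on a stable
    conventional core and successive signals grow more alike over turns.

    Returns (tags, novel) where ``novel`` is True on the re-construal branch.
    """
    if not prev:
        raise ValueError("evolve_signal needs a non-empty previous tag set")
    if rng.random() < behaviour.rho_reuse:
        tags = sorted(prev)
        p_drop = behaviour.delta_drop / (1 + max(0, level))
        kept = [t for t in tags if rng.random() >= p_drop]
        if not kept:
            kept = [tags[int(rng.integers(len(tags)))]]
        return frozenset(kept), False
    return sample_ground(item, ground, rng), True


def simulate_tagger(
    true_tags: frozenset[str], profile: TaggerProfile, rng: np.random.Generator
) -> frozenset[str]:
    """A tagger's coding of a signal: each true element detected with
    probability ``detection`` and renamed through the tagger's bijection."""
    out = set()
    for t in sorted(true_tags):
        if rng.random() < profile.detection:
            out.add(profile.relabel[t])
    return frozenset(out)


def simulate_responses(
    records: pd.DataFrame, behaviour: BehaviourModel, rng: np.random.Generator
) -> pd.DataFrame:
    """Generate accuracy, insight, iconicity and familiarity for signal records.

    ``records`` must carry jd_true, fam_sim, time_seen, log_pc and
    is_first_exposure.  Familiarity ratings are absent (NaN) on an item's
    first signal, where no predecessor exists to compare against.
    """
    needed = ["jd_true", "fam_sim", "time_seen", "log_pc", "is_first_exposure"]
    for col in needed:
        if col not in records.columns:
            raise DataIntegrityError(f"simulate_responses: missing covariate column {col!r}")
        bad = records[col].isna()
        if col != "fam_sim" and bad.any():
            raise DataIntegrityError(
                f"simulate_responses: covariate {col!r} missing for record "
                f"{records.loc[bad, 'signal_id'].iloc[0] if 'signal_id' in records else bad.idxmax()}"
            )
    out = records.copy()
    n = len(out)
    first = out["is_first_exposure"].to_numpy(dtype=bool)
    fam = out["fam_sim"].fillna(0.0).to_numpy(dtype=float)
    jd = out["jd_true"].to_numpy(dtype=float)
    time_seen = out["time_seen"].to_numpy(dtype=float)
    logpc = out["log_pc"].to_numpy(dtype=float)
    b = behaviour

    latent = (
        b.b0
        + b.b_jd * jd * first
        - b.b_fam * fam
        - b.b_time * (time_seen - 1)
        + rng.normal(scale=b.sigma_insight, size=n)
    )
    out["insight"] = np.clip(np.rint(latent), 1, 7).astype(int)

    logit = b.g0 + b.g_jd * jd + b.g_fam * fam + b.g_pc * (logpc - b.pc_ref)
    out["accuracy"] = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)

    rater_sd = 1.0 / np.sqrt(b.n_raters)
    icon = (
        b.icon0
        - b.icon_jd * jd
        - b.icon_time * (time_seen - 1)
        + rng.normal(scale=b.sigma_iconicity * rater_sd, size=n)
    )
    out["iconicity"] = np.clip(icon, 1.0, 7.0)

    famr = 1.0 + 6.0 * fam + rng.normal(scale=b.sigma_familiarity * rater_sd, size=n)
    famr = np.clip(famr, 1.0, 7.0)
    famr[first] = np.nan  # no familiarity rating is possible for a first signal
    out["familiarity"] = famr
    return out


# --------------------------------------------------------------------------- #
# whole-study simulation
# --------------------------------------------------------------------------- #


@dataclass
class StudyConfig:
    """Everything that defines a synthetic study (the defaults are the study
    conditions: 20 pairs, 25 items, 8 rounds, shortlist 10, two taggers)."""

    n_pairs: int = 20
    items: tuple[str, ...] = DEFAULT_ITEMS
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    behaviour: BehaviourModel = field(default_factory=BehaviourModel)
    vocab_size: int = 12
    lam: float = 4.0
    theta: float = 2.0
    theta_log_spread: float = 0.8
    n_taggers: int = 2
    tagger_detection: float = 0.9
    jd_mc_pairs: int = 400  # Monte-Carlo pairs for the generating expected JD

    def to_dict(self) -> dict:
        d = asdict(self)
        d["items"] = list(self.items)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "items" in d:
            d["items"] = tuple(d["items"])
        if isinstance(d.get("schedule"), dict):
            d["schedule"] = ScheduleConfig(**d["schedule"])
        if isinstance(d.get("behaviour"), dict):
            d["behaviour"] = BehaviourModel.from_dict(d["behaviour"])
        return cls(**d)


@dataclass
class StudyData:
    """In-memory synthetic study: tables, truth, and (optionally) images."""

    signals: pd.DataFrame  # one row per drawing event with covariates + responses
    tags: pd.DataFrame  # tagger codings of first-exposure signals
    jd: pd.DataFrame  # per item x tagger (+ consensus) JD_mu
    schedules: list[GameSchedule]
    truth: dict
    images: dict[str, np.ndarray] | None = None


def simulate_study(
    config: StudyConfig = StudyConfig(),
    seed: int = 0,
    keep_images: bool = False,
) -> StudyData:
    """Simulate a complete study (see module docstring).

    Deterministic under (config, seed); independent random streams are spawned
    for the ground model, schedules, signal evolution, taggers and responses
    so that, e.g., adding taggers does not perturb the schedules.
    """
    ss = np.random.SeedSequence(seed)
    s_ground, s_sched, s_evolve, s_tag, s_resp, s_jd = [
        np.random.default_rng(c) for c in ss.spawn(6)
    ]

    ground = GroundModel.build(
        items=config.items,
        seed=s_ground,
        vocab_size=config.vocab_size,
        lam=config.lam,
        theta=config.theta,
        theta_log_spread=config.theta_log_spread,
    )
    jd_true = {it: ground.expected_jd(it, s_jd, config.jd_mc_pairs) for it in config.items}
    taggers = [
        TaggerProfile.build(f"tagger{k + 1}", ground, s_tag, config.tagger_detection)
        for k in range(config.n_taggers)
    ]
    glyphs = GlyphLibrary()

    frames: list[pd.DataFrame] = []
    schedules: list[GameSchedule] = []
    true_tags: dict[str, frozenset[str]] = {}
    images: dict[str, np.ndarray] = {}

    for p in range(config.n_pairs):
        pair_id = f"pair{p:02d}"
        sched = build_schedule(
            config.items,
            config.schedule,
            seed=int(s_sched.integers(2**31)),
            pair_id=pair_id,
        )
        schedules.append(sched)
        rec = signal_records(sched)

        # evolve grounds along each item history, render, measure complexity
        state: dict[str, tuple[frozenset[str], int]] = {}
        tag_col, level_col, novel_col, logpc_col, pc_col, ink_col = [], [], [], [], [], []
        for row in rec.sort_values(["round", "signal_id"]).itertuples():
            if row.item not in state:
                tags = sample_ground(row.item, ground, s_evolve)
                level, novel = 0, True
            else:
                prev_tags, prev_level = state[row.item]
                tags, novel = evolve_signal(
                    prev_tags, row.item, config.behaviour, ground, s_evolve, level=prev_level
                )
                level = 0 if novel else prev_level + 1
            state[row.item] = (tags, level)
            img = render_signal(tags, level, glyphs)
            res = perimetric_complexity(img)
            true_tags[row.signal_id] = tags
            if keep_images:
                images[row.signal_id] = img
            tag_col.append("|".join(sorted(tags)))
            level_col.append(level)
            novel_col.append(novel)
            logpc_col.append(res.log_pc)
            pc_col.append(res.pc)
            ink_col.append(res.ink)
        rec = rec.sort_values(["round", "signal_id"]).reset_index(drop=True)
        rec["true_tags"] = tag_col
        rec["simplification_level"] = level_col
        rec["novel_construal"] = novel_col
        rec["log_pc"] = logpc_col
        rec["pc"] = pc_col
        rec["ink"] = ink_col

        # familiarity chain per item, resemblance = Jaccard similarity of true tags
        def resemblance(a: str, b: str) -> float:
            return 1.0 - jaccard_distance(true_tags[a], true_tags[b])

        pred = {}
        for item, grp in rec.groupby("item"):
            pred.update(link_familiarity_chain(grp, resemblance))
        rec["chain_predecessor"] = [pred.get(s) for s in rec.signal_id]
        rec["fam_sim"] = [
            np.nan if q is None else resemblance(s, q)
            for s, q in zip(rec.signal_id, rec.chain_predecessor)
        ]
        frames.append(rec)

    if frames:
        signals = pd.concat(frames, ignore_index=True)
        signals["jd_true"] = signals["item"].map(jd_true)
        signals = simulate_responses(signals, config.behaviour, s_resp)
    else:  # zero pairs: empty but schema-valid tables
        signals = pd.DataFrame(
            columns=[
                "pair_id", "round", "turn", "item", "signaller_id", "receiver_id",
                "signal_id", "is_first_exposure", "time_seen", "true_tags",
                "simplification_level", "novel_construal", "log_pc", "pc", "ink",
                "chain_predecessor", "fam_sim", "jd_true", "insight", "accuracy",
                "iconicity", "familiarity",
            ]
        )

    # receiver guesses: the item if correct, another pool item otherwise
    other = {
        it: [o for o in config.items if o != it] for it in config.items
    }
    signals["guess"] = [
        it if acc else other[it][int(s_resp.integers(len(other[it])))]
        for it, acc in zip(signals["item"], signals["accuracy"])
    ]

    # tagger codings of first-exposure signals, pooled across pairs per item
    tag_rows = []
    first_rows = signals[signals.is_first_exposure.astype(bool)].sort_values("signal_id")
    for tg in taggers:
        for row in first_rows.itertuples():
            coded = simulate_tagger(true_tags[row.signal_id], tg, s_tag)
            tag_rows.append(
                {
                    "signal_id": row.signal_id,
                    "item": row.item,
                    "tagger_id": tg.tagger_id,
                    "tags": "|".join(sorted(coded)),
                }
            )
    tags_df = pd.DataFrame(tag_rows, columns=["signal_id", "item", "tagger_id", "tags"])
    jd_df = jd_table(tags_df)

    cons = jd_df[jd_df.tagger == "consensus"].set_index("item")["jd_mu"]
    signals["jd_mu"] = signals["item"].map(cons)

    truth = {
        "seed": seed,
        "config": config.to_dict(),
        "ground_model": ground.to_dict(),
        "behaviour_model": config.behaviour.to_dict(),
        "jd_true": jd_true,
    }
    return StudyData(
        signals=signals,
        tags=tags_df,
        jd=jd_df,
        schedules=schedules,
        truth=truth,
        images=images if keep_images else None,
    )


def jd_table(tags_df: pd.DataFrame) -> pd.DataFrame:
    """Per-item, per-tagger JD_mu plus the cross-tagger consensus.

    Items with fewer than two coded first-exposure signals are excluded with
    a logged reason.
    """
    rows: list[ItemJD] = []
    if tags_df.empty:
        return pd.DataFrame(columns=["item", "tagger", "jd_mu", "n_signals", "n_pairs"])
    for (item, tagger), grp in tags_df.groupby(["item", "tagger_id"]):
        sets = [
            TagSet.make(r.signal_id, item, tagger, r.tags.split("|") if r.tags else [])
            for r in grp.itertuples()
        ]
        if len(sets) < 2:
            logger.info("JD_mu undefined for item %r / %s: %d signal(s)", item, tagger, len(sets))
            continue
        rows.append(item_jd_mean(sets))
    by_item: dict[str, list[ItemJD]] = {}
    for j in rows:
        by_item.setdefault(j.item_id, []).append(j)
    rows.extend(consensus_jd(v) for v in by_item.values())
    out = pd.DataFrame(
        [
            {
                "item": j.item_id,
                "tagger": j.tagger_id,
                "jd_mu": j.jd_mu,
                "n_signals": j.n_signals,
                "n_pairs": j.n_pairs,
            }
            for j in rows
        ],
        columns=["item", "tagger", "jd_mu", "n_signals", "n_pairs"],
    )
    return out.sort_values(["item", "tagger"]).reset_index(drop=True)


# --------------------------------------------------------------------------- #
# on-disk study
# --------------------------------------------------------------------------- #

_FLOAT_FMT = "%.10g"


def generate_study(
    config: StudyConfig,
    seed: int,
    out_dir: str | Path,
    force: bool = False,
    write_images: bool = True,
) -> StudyData:
    """Simulate a study and write it to ``out_dir``.

    Writes schedule.csv, signals.csv, tags.csv, jd.csv, responses.csv,
    ratings.csv, truth.json and (optionally) an images/ directory of PNGs.
    The directory must be empty unless ``force`` is given.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    existing = [p for p in out.iterdir() if not p.name.startswith(".")]
    if existing and not force:
        raise ConfigurationError(
            f"output directory {out} is not empty (pass force=True to overwrite)"
        )

    data = simulate_study(config, seed, keep_images=write_images)

    sched = pd.concat([s.to_frame() for s in data.schedules], ignore_index=True) if data.schedules else pd.DataFrame(
        columns=["pair_id", "round", "turn", "position", "item", "signaller_id", "receiver_id"]
    )
    _write_csv(sched, out / "schedule.csv")

    sig_cols = [
        "signal_id", "pair_id", "round", "turn", "item", "signaller_id",
        "is_first_exposure", "time_seen", "chain_predecessor",
        "simplification_level", "ink", "pc", "log_pc", "fam_sim",
    ]
    sig = data.signals.reindex(columns=sig_cols).copy()
    if write_images:
        sig["image_path"] = "images/" + data.signals["signal_id"] + ".png"
    _write_csv(sig, out / "signals.csv")
    _write_csv(data.tags, out / "tags.csv")
    _write_csv(data.jd, out / "jd.csv")
    resp = data.signals.reindex(
        columns=["signal_id", "pair_id", "receiver_id", "item", "guess", "accuracy", "insight"]
    )
    _write_csv(resp, out / "responses.csv")
    ratings = data.signals.reindex(columns=["signal_id", "item", "iconicity", "familiarity"])
    _write_csv(ratings, out / "ratings.csv")
    (out / "truth.json").write_text(json.dumps(data.truth, indent=2, sort_keys=True))

    if write_images and data.images is not None:
        from PIL import Image

        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        for sid in sorted(data.images):
            arr = np.where(data.images[sid], 0, 255).astype(np.uint8)  # ink = black
            Image.fromarray(arr, mode="L").save(img_dir / f"{sid}.png")
    return data


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
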