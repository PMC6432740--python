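"""Synthetic delayed-reproduction experiments with model-generated responses.

Three designs are generated, matching the structure of a working-memory
study with faces and gratings:

* Experiment 1A — faces only.  Five 600-trial blocks at set sizes 1-5;
  within a block each of 60 face identities is probed 10 times, twice
  with each of five emotions (angry, disgusted, fearful, happy, sad),
  once below and once above 50% expression intensity.  Targets take 10
  levels uniformly spanning 10% to 91%.  An optional final 300-trial
  set-size-1 block probes every identity-emotion combination once.
* Experiment 1B — gratings only, random orientations, 600 trials at each
  of set sizes 1, 3 and 5.
* Experiment 1C — mixed arrays of one face plus one or three gratings;
  either the face or a grating is probed.

Responses are produced by the population model under a dual-resource
rule: expression and orientation draw on separate gain pools.  The
effective load for a probed expression is the number of faces in the
array; for a probed orientation it is the number of gratings plus
``w`` times the number of faces, where w in [0, 1] is how much of the
orientation resource a face consumes (faces carry task-irrelevant
orientation structure; default w = 1, a face costs one full slot).  This
rule makes orientation recall degrade when faces are added while
expression recall is untouched by added gratings.

Tables are plain pandas DataFrames with one row per item and a
``probed`` flag; exactly one item per trial is probed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping

import numpy as np
import pandas as pd

from . import _engine
from .population import decoding_grid
from .spaces import BoundedSpace, CircularSpace

__all__ = [
    "EMOTIONS",
    "INTENSITY_LEVELS",
    "EXPRESSION_SPACE",
    "ORIENTATION_SPACE",
    "GeneratingModel",
    "design_exp1a",
    "design_exp1b",
    "design_exp1c",
    "design_mixed",
    "generate_responses",
    "probed_trials",
]

EMOTIONS = ("angry", "disgusted", "fearful", "happy", "sad")

#: The 10 design intensity levels, uniformly spanning 10% to 91%.
INTENSITY_LEVELS = np.linspace(10.0, 91.0, 10)

EXPRESSION_SPACE = BoundedSpace(0.0, 100.0)
ORIENTATION_SPACE = CircularSpace(180.0)

COLUMNS = [
    "participant",
    "experiment",
    "block",
    "trial",
    "set_size",
    "item_kind",
    "emotion",
    "identity",
    "target",
    "response",
    "probed",
]

_N_IDENTITIES = 60


@dataclass(frozen=True)
class GeneratingModel:
    """Generative parameters for synthetic responses.

    Emotion-specific gain constants set how precisely each expression is
    stored (defaults are ordered happy > disgusted > angry > fearful >
    sad, the precision ordering the model should recover); widths are in
    % intensity for expression and doubled-angle radians for
    orientation.  All values sit in the interior of the fitting grids so
    recovery is well posed.
    """

    emotion_gains: Mapping[str, float] = field(
        default_factory=lambda: {
            "happy": 9.0,
            "disgusted": 7.5,
            "angry": 6.0,
            "fearful": 4.5,
            "sad": 3.0,
        }
    )
    expression_width: float = 8.0
    orientation_gain: float = 20.0
    orientation_width: float = 0.5
    face_orientation_load: float = 1.0
    n_neurons: int = 1000
    expression_decoder: str = "posterior_sampling"
    orientation_decoder: str = "ml"

    def __post_init__(self) -> None:
        for name, g in self.emotion_gains.items():
            if name not in EMOTIONS:
                raise ValueError(f"unknown emotion {name!r}")
            if not g > 0:
                raise ValueError(f"gain for {name!r} must be positive")
        if not (self.expression_width > 0 and self.orientation_width > 0):
            raise ValueError("tuning widths must be positive")
        if not self.orientation_gain > 0:
            raise ValueError("orientation_gain must be positive")
        if not 0.0 <= self.face_orientation_load <= 1.0:
            raise ValueError("face_orientation_load must lie in [0, 1]")
        _engine.check_decoder(self.expression_decoder)
        _engine.check_decoder(self.orientation_decoder)

    def with_gains(self, **gains: float) -> "GeneratingModel":
        merged = dict(self.emotion_gains) | gains
        return replace(self, emotion_gains=merged)


def _frame(cols: Dict[str, list]) -> pd.DataFrame:
    df = pd.DataFrame(cols)[COLUMNS]
    df["probed"] = df["probed"].astype(bool)
    return df


def _balanced_levels(rng: np.random.Generator, half: np.ndarray) -> np.ndarray:
    """Assign 60 identities one level each from 5 levels, 12 identities per level."""
    levels = np.repeat(half, _N_IDENTITIES // len(half))
    rng.shuffle(levels)
    return levels


def design_exp1a(
    n_participants: int,
    rng: np.random.Generator,
    final_block: bool = False,
) -> pd.DataFrame:
    """Experiment-1A trial table (responses empty)."""
    if n_participants < 1:
        raise ValueError("n_participants must be at least 1")
    low, high = INTENSITY_LEVELS[:5], INTENSITY_LEVELS[5:]
    cols: Dict[str, list] = {c: [] for c in COLUMNS}
    identities = np.arange(1, _N_IDENTITIES + 1)
    for pid in range(1, n_participants + 1):
        trial_no = 0
        blocks = [(b, b, False) for b in range(1, 6)]
        if final_block:
            blocks.append((6, 1, True))
        for block, set_size, is_final in blocks:
            probes = []
            if is_final:
                # every identity-emotion combination once, random level
                for ident in identities:
                    for emo in EMOTIONS:
                        probes.append((ident, emo, float(rng.choice(INTENSITY_LEVELS))))
            else:
                for emo in EMOTIONS:
                    lo = _balanced_levels(rng, low)
                    hi = _balanced_levels(rng, high)
                    for k, ident in enumerate(identities):
                        probes.append((ident, emo, float(lo[k])))
                        probes.append((ident, emo, float(hi[k])))
            order = rng.permutation(len(probes))
            for t in order:
                ident, emo, level = probes[t]
                trial_no += 1
                others = rng.choice(identities[identities != ident], size=set_size - 1, replace=False)
                kinds = ["face"] * set_size
                emos = [emo] + [str(rng.choice(EMOTIONS)) for _ in range(set_size - 1)]
                ids = [ident] + list(others)
                targets = [level] + [float(rng.choice(INTENSITY_LEVELS)) for _ in range(set_size - 1)]
                probed = [True] + [False] * (set_size - 1)
                cols["participant"].extend([pid] * set_size)
                cols["experiment"].extend(["1A"] * set_size)
                cols["block"].extend([block] * set_size)
                cols["trial"].extend([trial_no] * set_size)
                cols["set_size"].extend([set_size] * set_size)
                cols["item_kind"].extend(kinds)
                cols["emotion"].extend(emos)
                cols["identity"].extend(ids)
                cols["target"].extend(targets)
                cols["response"].extend([np.nan] * set_size)
                cols["probed"].extend(probed)
    return _frame(cols)


def design_exp1b(
    n_participants: int,
    rng: np.random.Generator,
    n_trials_per_set: int = 600,
    set_sizes=(1, 3, 5),
) -> pd.DataFrame:
    """Experiment-1B trial table: grating-only arrays, random orientations."""
    if n_participants < 1:
        raise ValueError("n_participants must be at least 1")
    frames = []
    for pid in range(1, n_participants + 1):
        trial_offset = 0
        for block, s in enumerate(set_sizes, start=1):
            n = n_trials_per_set
            orientations = rng.uniform(0.0, 180.0, size=(n, s))
            probed_idx = rng.integers(0, s, size=n)
            trial_ids = trial_offset + np.arange(1, n + 1)
            trial_offset += n
            item_pos = np.tile(np.arange(s), n)
            frames.append(
                pd.DataFrame(
                    {
                        "participant": pid,
                        "experiment": "1B",
                        "block": block,
                        "trial": np.repeat(trial_ids, s),
                        "set_size": s,
                        "item_kind": "grating",
                        "emotion": pd.NA,
                        "identity": pd.NA,
                        "target": orientations.ravel(),
                        "response": np.nan,
                        "probed": item_pos == np.repeat(probed_idx, s),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)[COLUMNS]


def design_exp1c(
    n_participants: int,
    rng: np.random.Generator,
    n_trials_per_condition: int = 600,
) -> pd.DataFrame:
    """Experiment-1C trial table: one face plus one or three gratings.

    The probed item is chosen uniformly at random among the array items,
    so both face-probe and grating-probe trials occur; face emotions are
    drawn uniformly from the five emotions and intensities from the 10
    design levels.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be at least 1")
    cols: Dict[str, list] = {c: [] for c in COLUMNS}
    for pid in range(1, n_participants + 1):
        trial_no = 0
        for block, n_gratings in enumerate((1, 3), start=1):
            s = 1 + n_gratings
            for _ in range(n_trials_per_condition):
                trial_no += 1
                probe_pos = int(rng.integers(0, s))
                kinds = ["face"] + ["grating"] * n_gratings
                emos = [str(rng.choice(EMOTIONS))] + [pd.NA] * n_gratings
                ids = [int(rng.integers(1, _N_IDENTITIES + 1))] + [pd.NA] * n_gratings
                targets = [float(rng.choice(INTENSITY_LEVELS))] + list(
                    rng.uniform(0.0, 180.0, size=n_gratings)
                )
                cols["participant"].extend([pid] * s)
                cols["experiment"].extend(["1C"] * s)
                cols["block"].extend([block] * s)
                cols["trial"].extend([trial_no] * s)
                cols["set_size"].extend([s] * s)
                cols["item_kind"].extend(kinds)
                cols["emotion"].extend(emos)
                cols["identity"].extend(ids)
                cols["target"].extend(targets)
                cols["response"].extend([np.nan] * s)
                cols["probed"].extend([i == probe_pos for i in range(s)])
    return _frame(cols)


def design_mixed(
    n_trials: int,
    n_faces: int,
    n_gratings: int,
    probe: str,
    rng: np.random.Generator,
    participant: int = 1,
) -> pd.DataFrame:
    """Fixed-composition arrays probing one item kind on every trial.

    A building block for interference analyses: e.g. compare
    grating-probe recall between arrays of one grating with and without
    an accompanying face.  ``probe`` is "face" or "grating".
    """
    if probe not in ("face", "grating"):
        raise ValueError(f"probe must be 'face' or 'grating', got {probe!r}")
    if (probe == "face" and n_faces < 1) or (probe == "grating" and n_gratings < 1):
        raise ValueError(f"cannot probe a {probe} in an array with none")
    s = n_faces + n_gratings
    cols: Dict[str, list] = {c: [] for c in COLUMNS}
    for t in range(1, n_trials + 1):
        kinds = ["face"] * n_faces + ["grating"] * n_gratings
        emos = [str(rng.choice(EMOTIONS)) for _ in range(n_faces)] + [pd.NA] * n_gratings
        ids = [int(rng.integers(1, _N_IDENTITIES + 1)) for _ in range(n_faces)] + [pd.NA] * n_gratings
        targets = [float(rng.choice(INTENSITY_LEVELS)) for _ in range(n_faces)] + list(
            rng.uniform(0.0, 180.0, size=n_gratings)
        )
        if probe == "face":
            probe_pos = int(rng.integers(0, n_faces))
        else:
            probe_pos = n_faces + int(rng.integers(0, n_gratings))
        cols["participant"].extend([participant] * s)
        cols["experiment"].extend(["custom"] * s)
        cols["block"].extend([1] * s)
        cols["trial"].extend([t] * s)
        cols["set_size"].extend([s] * s)
        cols["item_kind"].extend(kinds)
        cols["emotion"].extend(emos)
        cols["identity"].extend(ids)
        cols["target"].extend(targets)
        cols["response"].extend([np.nan] * s)
        cols["probed"].extend([i == probe_pos for i in range(s)])
    return _frame(cols)


def probed_trials(design: pd.DataFrame) -> pd.DataFrame:
    """The probed item of every trial (the rows fitting and stats consume)."""
    return design[design["probed"].astype(bool)].reset_index(drop=True)


def generate_responses(
    design: pd.DataFrame,
    model: GeneratingModel,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Fill in model-generated responses for every probed item.

    The probed feature is encoded with per-item gain gamma/N_eff, where
    N_eff follows the dual-resource rule described in the module
    docstring, then decoded with the model's read-out for that feature.
    """
    df = design.copy()
    probed = df["probed"].astype(bool).to_numpy()
    per_trial = df.groupby(["participant", "trial"], sort=False)
    if not (per_trial["probed"].transform("sum").to_numpy() == 1)[probed].all():
        raise ValueError("each trial must contain exactly one probed item")
    if df.loc[probed, "response"].notna().any():
        raise ValueError("design already contains responses")
    is_face = (df["item_kind"] == "face").astype(float)
    n_faces = df.assign(_f=is_face).groupby(["participant", "trial"], sort=False)["_f"].transform("sum")
    n_gratings = df.assign(_g=(df["item_kind"] == "grating").astype(float)).groupby(
        ["participant", "trial"], sort=False
    )["_g"].transform("sum")

    pidx = np.flatnonzero(probed)
    kind = df["item_kind"].to_numpy()[pidx]
    targets = df["target"].to_numpy(dtype=float)[pidx]
    nf = n_faces.to_numpy()[pidx]
    ng = n_gratings.to_numpy()[pidx]
    responses = np.full(len(pidx), np.nan)

    face_sel = kind == "face"
    if face_sel.any():
        if np.any(nf[face_sel] < 1):  # pragma: no cover - impossible by construction
            raise ValueError("probed face in a face-free array")
        emotions = df["emotion"].to_numpy()[pidx][face_sel]
        gains = np.array([model.emotion_gains[e] for e in emotions])
        totals = gains / nf[face_sel]
        grid = decoding_grid(EXPRESSION_SPACE)
        log_prior = _engine.log_prior_weights(EXPRESSION_SPACE, grid, None)
        responses[face_sel] = _engine.simulate_batch(
            EXPRESSION_SPACE, model.expression_width, totals, targets[face_sel],
            model.expression_decoder, grid, log_prior, rng, model.n_neurons,
        )
    grat_sel = kind == "grating"
    if grat_sel.any():
        if np.any(ng[grat_sel] < 1):
            raise ValueError("probed grating in a grating-free array")
        n_eff = ng[grat_sel] + model.face_orientation_load * nf[grat_sel]
        totals = model.orientation_gain / n_eff
        grid = decoding_grid(ORIENTATION_SPACE)
        log_prior = _engine.log_prior_weights(ORIENTATION_SPACE, grid, None)
        responses[grat_sel] = _engine.simulate_batch(
            ORIENTATION_SPACE, model.orientation_width, totals, targets[grat_sel],
            model.orientation_decoder, grid, log_prior, rng, model.n_neurons,
        )
    out = df["response"].to_numpy(dtype=float)
    out[pidx] = responses
    df["response"] = out
    return df
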