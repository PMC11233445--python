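"""Delimited-text readers and writers for every pipeline artifact.

All files are UTF-8 CSV with a header row: trials (one row per response
event, kana allowed), stimulus metadata (one row per stimulus, mirroring
the study's stimulus table), participant metadata, long-format fusion
tables, parameter tables (role, id, value), and prediction tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import NEDParams
from .scoring import FusionTable, StimulusSpec, make_congruent_spec, make_stimulus_spec

TRIAL_COLUMNS = [
    "participant_id", "stimulus_id", "repetition", "stimulus_kind", "raw_response",
]


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str, "stimulus_id": str})
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing trial columns {sorted(missing)}")
    return df[TRIAL_COLUMNS]


def write_trials(trials: pd.DataFrame, path) -> None:
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_stimulus_specs(path) -> dict[str, StimulusSpec]:
    """Stimulus metadata CSV -> spec mapping (file order preserved).

    Columns: stimulus_id, auditory, visual, voicing (voiced/unvoiced),
    talker_gender, talker_native_japanese (true/false); optional
    fusion_percept and kind (mcgurk/congruent, default mcgurk).
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    specs: dict[str, StimulusSpec] = {}
    for row in df.itertuples(index=False):
        kind = getattr(row, "kind", "") or "mcgurk"
        if kind == "congruent":
            specs[row.stimulus_id] = make_congruent_spec(
                row.stimulus_id, row.auditory, talker_gender=row.talker_gender
            )
        else:
            specs[row.stimulus_id] = make_stimulus_spec(
                row.stimulus_id,
                row.auditory,
                row.visual,
                row.voicing,
                talker_gender=row.talker_gender,
                talker_native_japanese=str(row.talker_native_japanese).lower()
                in ("true", "yes", "1"),
                fusion_percept=getattr(row, "fusion_percept", "") or None,
            )
    return specs


def write_stimulus_specs(specs: dict[str, StimulusSpec], path) -> None:
    rows = [
        {
            "stimulus_id": s.stimulus_id,
            "auditory": s.auditory_syllable,
            "visual": s.visual_syllable,
            "fusion_percept": s.fusion_percept,
            "voicing": s.voicing,
            "talker_gender": s.talker_gender,
            "talker_native_japanese": s.talker_native_japanese,
            "kind": "congruent" if not s.fusion_forms else "mcgurk",
        }
        for s in specs.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_participant_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    if "participant_id" not in df.columns:
        raise ValueError(f"{path}: missing participant_id column")
    return df


def write_fusion_table(table: FusionTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_fusion_table(path) -> FusionTable:
    return FusionTable.from_frame(
        pd.read_csv(path, dtype={"participant_id": str, "stimulus_id": str})
    )


def write_params(params: NEDParams, path) -> None:
    params.to_frame().to_csv(path, index=False)


def read_params(path) -> NEDParams:
    df = pd.read_csv(path, dtype={"id": str})
    d = df[df["role"] == "disparity"]
    t = df[df["role"] == "threshold"]
    s = df[df["role"] == "sigma"]
    return NEDParams(
        D=d["value"].to_numpy(float),
        T=t["value"].to_numpy(float),
        sigma=s["value"].to_numpy(float),
        stimuli=list(d["id"]),
        participants=list(t["id"]),
    )


def write_predictions(observed: FusionTable, predicted: np.ndarray, path) -> None:
    """Cell-level predictions table (missing cells omitted)."""
    rows = []
    for j, pid in enumerate(observed.participants):
        for i, sid in enumerate(observed.stimuli):
            obs = observed.fusion_prop[j, i]
            if np.isnan(obs):
                continue
            rows.append(
                {
                    "participant_id": pid,
                    "stimulus_id": sid,
                    "observed": obs,
                    "predicted": predicted[j, i],
                    "abs_error": abs(predicted[j, i] - obs),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_exclusions(excluded: list[tuple[str, float]], path) -> None:
    pd.DataFrame(excluded, columns=["participant_id", "congruent_accuracy"]).to_csv(
        path, index=False
    )
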