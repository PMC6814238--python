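"""Dataset container and tidy-CSV serialization.

A :class:`Dataset` holds everything one experiment produces: the dial event
logs, the overall judgments, and participant/stimulus metadata (including,
for simulated data, the generating parameters used by parameter-recovery
tests).  Simulated and loaded datasets are interchangeable: the analysis
modules consume only the tidy tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig

__all__ = ["Dataset", "load_dataset", "SchemaError"]

EVENT_COLUMNS = ["participant_id", "group", "session", "category",
                 "stimulus_id", "t_sec", "position"]
OVERALL_COLUMNS = ["participant_id", "group", "session", "category",
                   "stimulus_id", "rating"]
TRIAL_KEYS = ["participant_id", "group", "session", "category", "stimulus_id"]


class SchemaError(ValueError):
    """Raised when an input table violates the dataset schema."""


def _check_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table is missing columns: {missing}")


def validate_events(events: pd.DataFrame, duration_s: float | None = None) -> None:
    _check_columns(events, EVENT_COLUMNS, "events")
    bad = events.index[(events["position"] < -1) | (events["position"] > 1)]
    if len(bad):
        raise SchemaError(
            f"position outside [-1, 1] at rows {list(bad[:5])} "
            f"(first value {events.loc[bad[0], 'position']!r})")
    if duration_s is not None:
        late = events.index[(events["t_sec"] < 0) | (events["t_sec"] >= duration_s)]
        if len(late):
            raise SchemaError(
                f"t_sec outside [0, {duration_s}) at rows {list(late[:5])}")
    for keys, grp in events.groupby(TRIAL_KEYS, sort=False):
        t = grp["t_sec"].to_numpy()
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise SchemaError(
                f"timestamps not strictly increasing within trial {keys}")


def validate_overall(overall: pd.DataFrame) -> None:
    _check_columns(overall, OVERALL_COLUMNS, "overall")
    bad = overall.index[(overall["rating"] < -1) | (overall["rating"] > 1)]
    if len(bad):
        raise SchemaError(f"rating outside [-1, 1] at rows {list(bad[:5])}")
    dup = overall.duplicated(subset=["participant_id", "stimulus_id", "session"])
    if dup.any():
        raise SchemaError(
            f"duplicate (participant, stimulus, session) overall-rating rows "
            f"at {list(overall.index[dup][:5])}")


@dataclass
class Dataset:
    events: pd.DataFrame
    overall: pd.DataFrame
    participants: pd.DataFrame
    stimuli: pd.DataFrame
    config: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        validate_events(self.events, self.config.duration_s)
        validate_overall(self.overall)
        view_test = self.events[(self.events["group"] == "view")
                                & (self.events["session"] == "test")]
        if len(view_test):
            warnings.warn(
                "continuous events present for the view group in the test "
                "session: the study design collects none; keeping the rows",
                stacklevel=2)

    def traces(self, groups: tuple[str, ...] | None = None,
               sessions: tuple[str, ...] | None = None) -> pd.DataFrame:
        """Wide table of zero-order-hold traces, one row per continuous trial.

        Index: the trial keys; columns: sample indices 0..n-1.
        """
        from .timeseries import traces_from_events

        ev = self.events
        if groups is not None:
            ev = ev[ev["group"].isin(groups)]
        if sessions is not None:
            ev = ev[ev["session"].isin(sessions)]
        # continuous trials follow the design rule, not the overall table
        from .synth import has_continuous_rating
        trials = self.overall[TRIAL_KEYS].drop_duplicates()
        mask = np.array([has_continuous_rating(g, s) for g, s in
                         zip(trials["group"], trials["session"])])
        trials = trials[mask]
        if groups is not None:
            trials = trials[trials["group"].isin(groups)]
        if sessions is not None:
            trials = trials[trials["session"].isin(sessions)]
        return traces_from_events(ev, trials, self.config.duration_s,
                                  self.config.sample_rate_hz)

    def write(self, out_dir: str | Path, force: bool = False) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        targets = {
            "events.csv": self.events,
            "overall.csv": self.overall,
            "participants.csv": self.participants,
            "stimuli.csv": self.stimuli,
        }
        for name in targets:
            if (out / name).exists() and not force:
                raise FileExistsError(
                    f"{out / name} exists; pass force=True to overwrite")
        for name, df in targets.items():
            df.to_csv(out / name, index=False, float_format="%.10g")
        self.config.to_yaml(out / "config.yaml")

    @classmethod
    def read(cls, in_dir: str | Path) -> "Dataset":
        inp = Path(in_dir)
        config = SimulationConfig.from_yaml(inp / "config.yaml")
        return cls(
            events=pd.read_csv(inp / "events.csv"),
            overall=pd.read_csv(inp / "overall.csv"),
            participants=pd.read_csv(inp / "participants.csv"),
            stimuli=pd.read_csv(inp / "stimuli.csv"),
            config=config,
        )

    def equals(self, other: "Dataset") -> bool:
        return (self.events.equals(other.events)
                and self.overall.equals(other.overall)
                and self.participants.equals(other.participants)
                and self.stimuli.equals(other.stimuli))


def load_dataset(events_csv: str | Path, overall_csv: str | Path,
                 config: SimulationConfig | None = None) -> Dataset:
    """Build a Dataset from user-supplied tidy CSV files.

    Participant and stimulus metadata tables are reconstructed from the keys
    present in the rating tables (generating parameters are unknown for real
    data).
    """
    events = pd.read_csv(events_csv)
    overall = pd.read_csv(overall_csv)
    config = config or SimulationConfig()
    participants = (overall[["participant_id", "group"]]
                    .drop_duplicates().reset_index(drop=True))
    stimuli = (overall[["stimulus_id", "category"]]
               .drop_duplicates().reset_index(drop=True))
    return Dataset(events=events, overall=overall, participants=participants,
                   stimuli=stimuli, config=config)
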