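"""Full study orchestration: simulate -> preprocess -> classify -> evaluate
-> extract ERP features -> correlate, for a whole cohort and both speller
modalities.

A :class:`StudyConfig` captures every parameter, serializes to a single
YAML file, and is hashed into the output manifest; re-running into the same
directory with a different configuration is refused instead of silently
overwriting.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .erp import average_erp, detect_components, independent_ttest, paired_ttest
from .performance import (
    NOT_REACHED,
    PerformanceRecord,
    accuracy_vs_repetitions,
    cross_validate,
    error_offset_matrix,
    mutual_information_itr,
    pierce_itr,
    reps_to_criterion,
    selection_time,
    selections_from_trials,
)
from .predict import (
    CorrelationMap,
    component_correlations,
    extract_oddball_amplitude_features,
    median_split,
    spearman_map,
)
from .preprocess import EpochSet, preprocess_recording
from .recording import TimingConfig
from .simulate import (
    ParticipantProfile,
    draw_cohort,
    simulate_bci_session,
    simulate_oddball_session,
)

__all__ = ["StudyConfig", "StudyResult", "run_study", "analyze_participant"]

logger = logging.getLogger(__name__)

_SESSION_SEED_OFFSET = {"oddball": 10007, "visual": 20011, "auditory": 30011}


def _session_seed(profile_seed: int, session: str) -> int:
    return (profile_seed + _SESSION_SEED_OFFSET[session]) % (2**31 - 1)


@dataclass
class StudyConfig:
    """Everything needed to reproduce one simulated study."""

    n_participants: int = 40
    seed: int = 0
    montage: str = "full63"
    modalities: tuple[str, ...] = ("visual", "auditory")
    timing: TimingConfig = field(default_factory=TimingConfig)
    bandpass_hz: tuple[float, float] = (0.5, 20.0)
    eog_corr_threshold: float = 0.7
    bss_lag: int = 1
    p_enter: float = 0.10
    p_remove: float = 0.15
    max_iter: int = 60
    ma_width: int = 25
    decim: int = 25
    criterion_percent: float = 70.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["modalities"] = list(self.modalities)
        d["bandpass_hz"] = list(self.bandpass_hz)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "timing" in d and isinstance(d["timing"], dict):
            d["timing"] = TimingConfig.from_dict(d["timing"])
        for key in ("modalities", "bandpass_hz"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _session_runs(epochs: EpochSet, n_runs: int) -> list[EpochSet]:
    runs = []
    run_ids = np.array([e.run_index for e in epochs.events])
    for r in range(n_runs):
        runs.append(epochs.subset(run_ids == r))
    return runs


def analyze_participant(
    profile: ParticipantProfile, config: StudyConfig
) -> tuple[dict, np.ndarray, np.ndarray, dict[str, PerformanceRecord], dict[str, list]]:
    """Run the full pipeline for one participant.

    Returns (erp feature dict, oddball amplitude grid, grid bin centers,
    per-modality performance records, per-modality (selections, targets)).
    """
    timing = config.timing
    low, high = config.bandpass_hz

    oddball = simulate_oddball_session(
        profile, timing, seed=_session_seed(profile.seed, "oddball")
    )
    odd_epochs = preprocess_recording(
        oddball, low, high, config.eog_corr_threshold, config.bss_lag
    )
    feats = extract_oddball_amplitude_features(odd_epochs, "component_peaks")
    grid, bin_centers = extract_oddball_amplitude_features(
        odd_epochs, "raw_grid", decim=config.decim
    )
    erp_row = {
        "participant_id": profile.participant_id,
        "aptitude": profile.aptitude,
        "n200_amp_uV": feats.n200_amp_uV,
        "n200_lat_ms": feats.n200_lat_ms,
        "p300_amp_uV": feats.p300_amp_uV,
        "p300_lat_ms": feats.p300_lat_ms,
        "late_amp_uV": feats.late_amp_uV,
        "late_lat_ms": feats.late_lat_ms,
        "degenerate": feats.degenerate,
    }

    records: dict[str, PerformanceRecord] = {}
    selections: dict[str, list] = {}
    for modality in config.modalities:
        rec = simulate_bci_session(
            profile, modality, timing, seed=_session_seed(profile.seed, modality)
        )
        epochs = preprocess_recording(
            rec, low, high, config.eog_corr_threshold, config.bss_lag
        )
        runs = _session_runs(epochs, timing.runs_per_session)
        trials = cross_validate(
            runs,
            p_enter=config.p_enter,
            p_remove=config.p_remove,
            max_iter=config.max_iter,
            ma_width=config.ma_width,
            decim=config.decim,
        )
        curve = accuracy_vs_repetitions(trials, max_reps=timing.sequences_per_letter)
        reps = reps_to_criterion(curve, config.criterion_percent)
        secs, spm = selection_time(min(reps, timing.sequences_per_letter), modality, timing)
        acc_full = float(curve.accuracy_percent[-1])
        records[modality] = PerformanceRecord(
            participant_id=profile.participant_id,
            modality=modality,
            accuracy_percent=acc_full,
            reps_to_criterion=reps,
            criterion=config.criterion_percent,
            selection_time_s=secs,
            selections_per_min=spm,
            itr_pierce_bits_per_min=pierce_itr(acc_full / 100.0, 25, spm),
            curve=curve,
        )
        selections[modality] = selections_from_trials(trials, timing.sequences_per_letter)
    return erp_row, grid, bin_centers, records, selections


@dataclass
class StudyResult:
    config: StudyConfig
    performance: pd.DataFrame
    erp_features: pd.DataFrame
    correlations: pd.DataFrame
    maps: dict[str, CorrelationMap]
    offset_matrices: dict[str, np.ndarray]
    mi_itr_bits_per_min: dict[str, float]
    groups: pd.DataFrame
    curves: dict[str, np.ndarray]
    group_tests: dict[str, dict] = field(default_factory=dict)


def run_study(config: StudyConfig, out_dir: str | Path | None = None, overwrite: bool = False) -> StudyResult:
    """Simulate and analyze a whole cohort.

    Writes, when ``out_dir`` is given: per-participant performance and ERP
    feature CSVs, the component correlation table, per-modality correlation
    map CSVs, and a JSON summary manifest carrying the config hash.
    """
    cohort = draw_cohort(config.n_participants, config.seed, config.montage)
    erp_rows, perf_rows, grids = [], [], []
    pooled: dict[str, tuple[list, list]] = {m: ([], []) for m in config.modalities}
    curves: dict[str, list] = {m: [] for m in config.modalities}
    for i, profile in enumerate(cohort):
        logger.info("participant %s (%d/%d)", profile.participant_id, i + 1, len(cohort))
        erp_row, grid, bin_centers, records, sels = analyze_participant(profile, config)
        erp_rows.append(erp_row)
        grids.append(grid)
        for modality, record in records.items():
            s, t = sels[modality]
            try:
                # a sparse per-participant offset matrix can leave some
                # target without reachable probability mass
                itr_mi = mutual_information_itr(
                    error_offset_matrix(s, t), record.selections_per_min
                )
            except ValueError:
                itr_mi = float("nan")
            perf_rows.append(
                {
                    "participant_id": record.participant_id,
                    "modality": modality,
                    "aptitude": profile.aptitude,
                    "accuracy_percent": record.accuracy_percent,
                    "reps_to_criterion": record.reps_to_criterion,
                    "reached": record.reached_criterion,
                    "selection_time_s": record.selection_time_s,
                    "selections_per_min": record.selections_per_min,
                    "itr_pierce_bits_per_min": record.itr_pierce_bits_per_min,
                    "itr_mi_bits_per_min": itr_mi,
                }
            )
            pooled[modality][0].extend(s)
            pooled[modality][1].extend(t)
            curves[modality].append(records[modality].curve.accuracy_percent)

    erp_features = pd.DataFrame(erp_rows)
    performance = pd.DataFrame(perf_rows)
    correlations = component_correlations(erp_features, performance)

    amplitudes = np.stack(grids)
    maps: dict[str, CorrelationMap] = {}
    offmats: dict[str, np.ndarray] = {}
    mi_itr: dict[str, float] = {}
    channel_labels = list(cohort[0].eeg_labels)
    for modality in config.modalities:
        perf_m = performance[performance.modality == modality].set_index("participant_id")
        perf_vec = perf_m.loc[erp_features.participant_id, "reps_to_criterion"].to_numpy()
        try:
            maps[modality] = spearman_map(amplitudes, perf_vec, channel_labels, bin_centers)
        except ValueError as exc:  # e.g. constant performance in tiny cohorts
            logger.warning("%s correlation map skipped: %s", modality, exc)
            maps[modality] = None
        offmats[modality] = error_offset_matrix(*pooled[modality])
        mean_spm = float(perf_m["selections_per_min"].mean())
        mi_itr[modality] = mutual_information_itr(offmats[modality], mean_spm)

    # median split on the mean of the modality metrics (single modality: itself)
    wide = performance.pivot(index="participant_id", columns="modality", values="reps_to_criterion")
    basis = wide.mean(axis=1).to_numpy()
    try:
        labels = median_split(basis)
    except ValueError:
        labels = np.array(["high"] * len(wide))
    groups = pd.DataFrame({"participant_id": wide.index, "group": labels, "split_basis": basis})

    # group statistics: modality comparison (paired) and high/low aptitude
    # component differences (independent, pooled variance)
    group_tests: dict[str, dict] = {}
    if {"visual", "auditory"} <= set(config.modalities):
        acc = performance.pivot(
            index="participant_id", columns="modality", values="accuracy_percent"
        )
        t = paired_ttest(acc["visual"].to_numpy(), acc["auditory"].to_numpy())
        group_tests["visual_vs_auditory_accuracy"] = {"t": t.t, "dof": t.dof, "p": t.p}
    merged_groups = erp_features.merge(groups, on="participant_id")
    if set(merged_groups.group) == {"high", "low"}:
        hi = merged_groups[merged_groups.group == "high"]
        lo = merged_groups[merged_groups.group == "low"]
        if len(hi) >= 2 and len(lo) >= 2:
            for col in ("n200_amp_uV", "p300_amp_uV", "late_amp_uV"):
                t = independent_ttest(hi[col].to_numpy(), lo[col].to_numpy())
                group_tests[f"high_vs_low_{col}"] = {"t": t.t, "dof": t.dof, "p": t.p}

    mean_curves = {m: np.mean(np.stack(v), axis=0) for m, v in curves.items()}
    result = StudyResult(
        config=config,
        performance=performance,
        erp_features=erp_features,
        correlations=correlations,
        maps=maps,
        offset_matrices=offmats,
        mi_itr_bits_per_min=mi_itr,
        groups=groups,
        curves=mean_curves,
        group_tests=group_tests,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir), overwrite)
    return result


def _write_outputs(result: StudyResult, out_dir: Path, overwrite: bool) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    summary_file = out_dir / "summary.json"
    if summary_file.exists():
        previous = json.loads(summary_file.read_text())
        if previous.get("config_hash") != result.config.config_hash and not overwrite:
            raise FileExistsError(
                f"{out_dir} holds results for config {previous.get('config_hash')}; "
                "refusing to overwrite with a different configuration"
            )
    files = {}
    tables = {
        "performance.csv": result.performance,
        "erp_features.csv": result.erp_features,
        "component_correlations.csv": result.correlations,
        "groups.csv": result.groups,
    }
    for modality, cmap in result.maps.items():
        if cmap is not None:
            tables[f"correlation_map_{modality}.csv"] = cmap.to_frame()
    for name, frame in tables.items():
        text = frame.to_csv(index=False, float_format="%.10g")
        (out_dir / name).write_text(text)
        files[name] = hashlib.sha1(text.encode()).hexdigest()[:12]
    summary = {
        "package_version": __version__,
        "config_hash": result.config.config_hash,
        "config": result.config.to_dict(),
        "mi_itr_bits_per_min": result.mi_itr_bits_per_min,
        "group_tests": result.group_tests,
        "map_extrema": {
            m: (c.extrema() if c is not None else None) for m, c in result.maps.items()
        },
        "mean_accuracy_percent": {
            m: float(
                result.performance.loc[result.performance.modality == m, "accuracy_percent"].mean()
            )
            for m in result.config.modalities
        },
        "mean_reps_to_criterion": {
            m: float(
                result.performance.loc[result.performance.modality == m, "reps_to_criterion"].mean()
            )
            for m in result.config.modalities
        },
        "file_hashes": files,
    }
    summary_file.write_text(json.dumps(summary, indent=1, sort_keys=True))
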