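"""End-to-end SAS screening pipeline: recordings -> segments -> features ->
k-means screen -> cohort report.

A run is described by a :class:`RunConfig` (YAML-serializable; CLI flags
override file values).  Every report embeds the full resolved
configuration, and reports are byte-identical across runs with the same
configuration and seeds.  Any stage failure aborts the run and removes
partial outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import cluster, io, segments, synthetic
from .types import BreathRecording, SasFlag

log = logging.getLogger("sasod")


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    input_dir: str | None = None      # directory of WAVs; None -> synthetic cohort
    seed: int = 0
    n_sas: int = 37                   # synthetic cohort composition
    n_non_sas: int = 5
    duration_s: float = 180.0
    rate: float = 8000.0
    binarize_threshold: float = 0.05
    apnea_min_duration_s: int = 8
    n_segments: int = 5
    segment_window_s: float = 15.0
    feature_scheme: str = "RMS_ENVELOPE_1S"
    k_range: tuple[int, ...] = (4, 5, 6, 7)
    n_init: int = 10
    square_center: float = 0.59
    square_half_width: float = 0.11

    def __post_init__(self) -> None:
        if not 0 < self.binarize_threshold < 1:
            raise ValueError("binarize_threshold must be in (0, 1)")
        if self.apnea_min_duration_s < 1:
            raise ValueError("apnea_min_duration_s must be >= 1")
        if self.n_segments < 1 or self.segment_window_s <= 0:
            raise ValueError("invalid segment extraction parameters")
        if any(k < 2 for k in self.k_range):
            raise ValueError("k_range entries must be >= 2")
        self.k_range = tuple(int(k) for k in self.k_range)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "k_range" in data:
            data["k_range"] = tuple(data["k_range"])
        return cls(**data)


def _load_cohort(config: RunConfig) -> list[BreathRecording]:
    if config.input_dir is None:
        log.info("generating synthetic cohort: %d SAS + %d healthy subjects",
                 config.n_sas, config.n_non_sas)
        return synthetic.gen_breath_cohort(
            n_sas=config.n_sas,
            n_non_sas=config.n_non_sas,
            duration_s=config.duration_s,
            rate=config.rate,
            seed=config.seed,
        )
    wavs = sorted(Path(config.input_dir).glob("*.wav"))
    if not wavs:
        raise FileNotFoundError(f"no WAV files found in {config.input_dir}")
    return [io.read_wav(p) for p in wavs]


def run_sas_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute segment -> features -> select_k_and_decide; write report.

    Returns the report dict; writes ``report.json``, ``manifest.csv`` and
    ``assignments.csv`` under ``outdir``.  On failure all partial outputs
    are removed and the stage's error re-raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        recordings = _load_cohort(config)
        seg_rows = []
        all_segments = []
        for rec in recordings:
            segs = segments.extract_segments(
                rec, n_segments=config.n_segments, window_s=config.segment_window_s
            )
            for j, s in enumerate(segs):
                all_segments.append(s)
                seg_rows.append(
                    {
                        "subject_id": s.subject_id,
                        "segment_index": j,
                        "center_s": round(s.center_s, 3),
                        "peak_pressure": round(s.peak_pressure, 6),
                        "sas_flag": s.sas_flag.value,
                    }
                )
        log.info("extracted %d segments from %d subjects",
                 len(all_segments), len(recordings))
        feats = [
            cluster.extract_features(s, config.feature_scheme) for s in all_segments
        ]
        labeled = all(f.sas_flag is not SasFlag.UNKNOWN for f in feats)
        model, calls, table = cluster.select_k_and_decide(
            feats,
            k_range=config.k_range,
            seed=config.seed,
            n_init=config.n_init,
        )
        manifest = outdir / "manifest.csv"
        pd.DataFrame(seg_rows).to_csv(manifest, index=False)
        written.append(manifest)
        assignments = outdir / "assignments.csv"
        pd.DataFrame(
            {
                "subject_id": [f.subject_id for f in feats],
                "sas_flag": [f.sas_flag.value for f in feats],
                "cluster": model.assignments,
            }
        ).to_csv(assignments, index=False)
        written.append(assignments)
        report = {
            "config": config.to_dict(),
            "n_subjects": len(recordings),
            "n_segments": len(all_segments),
            "selected_k": model.k,
            "silhouette": round(model.silhouette, 6),
            "inertia": round(model.inertia, 6),
            "cluster_table": {str(k): v for k, v in (table or {}).items()},
            "labeled_reference": labeled,
            "subject_calls": {k: bool(v) for k, v in (calls or {}).items()},
        }
        report_path = outdir / "report.json"
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        written.append(report_path)
        return report
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
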