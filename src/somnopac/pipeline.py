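"""End-to-end cohort analysis: simulate → score → standardize → PSD → PAC → stats.

``run_cohort_analysis`` drives the whole chain from a single declarative
configuration (YAML or an equivalent dict), writes tidy CSV tables plus a
run manifest (config hash, seed, package version), and is deterministic for
a fixed configuration and seed: re-running produces byte-identical CSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from importlib.metadata import PackageNotFoundError, version

import numpy as np
import pandas as pd
import yaml

from . import architecture as arch
from . import pac as pacmod
from . import preprocess as prep
from . import signal_io, spectral
from . import stats as gstats
from . import synthetic
from .core import STATES, ShortfallError, ValidationError

__all__ = ["load_config", "build_cohort_spec", "run_cohort_analysis"]

log = logging.getLogger("somnopac")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohort": {
        "duration_h": 24.0,
        "n_per_group": 5,
        "sampling_rate_hz": 400.0,
        "epoch_length_s": 10.0,
        "groups": {
            "control": {"coupling_strength": 0.8},
            "ko": {"coupling_strength": 0.2, "amplitude_scale": {"NREM": 0.5}},
        },
    },
    "analysis": {
        "eeg_channel": "EEG1",
        "hypnogram": "score",  # "score" (rule-based) or "truth" (generator labels)
        "standardize_s": {"WAKE": 15_000.0, "NREM": 10_000.0, "REM": 2_000.0},
        "bands": "figure",
        "block_hours": 12.0,
        "pac": {
            "method": "canolty",
            "phase_band": [6.0, 10.0],
            "amp_band": [80.0, 120.0],
            "n_surrogates": 100,
            "scheme": "circular_shift",
        },
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | os.PathLike | None = None, overrides: dict | None = None) -> dict:
    """Load a YAML config file, layered over the package defaults."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, user)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def build_cohort_spec(config: dict) -> synthetic.CohortSpec:
    c = config["cohort"]
    return synthetic.default_cohort_spec(
        n_per_group=int(c.get("n_per_group", 5)),
        duration_h=float(c.get("duration_h", 24.0)),
        seed=int(config.get("seed", 0)),
        group_settings=c.get("groups"),
    )


def _subject_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence(master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def run_cohort_analysis(config: dict, out_dir: str | os.PathLike) -> dict[str, pd.DataFrame]:
    """Run the full pipeline for every subject and write tidy CSV reports.

    Per subject and state: segment export on the (scored or ground-truth)
    hypnogram → concatenate/trim to the standardized duration → filter chain
    → Welch PSD and band powers → MI with a surrogate p-value. Group
    comparisons per metric follow, Holm-corrected across the family. A
    subject lacking enough data for a state is excluded from that state's
    comparisons with a logged reason.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    spec = build_cohort_spec(config)
    a = config["analysis"]
    bands = spectral.BAND_PRESETS[a.get("bands", "figure")]
    std_spec = prep.StandardizationSpec(
        targets_s={k: float(v) for k, v in a["standardize_s"].items()}
    )
    pac_cfg = a["pac"]
    master = int(config.get("seed", 0))

    arch_rows, band_rows, psd_rows, pac_rows = [], [], [], []
    exclusions: list[dict] = []

    for gi, (group, gspec) in enumerate(spec.groups.items()):
        for si in range(gspec.n_subjects):
            rec, true_hyp = synthetic.synthesize_recording(spec, group, si)
            if a.get("hypnogram", "score") == "truth":
                hyp = true_hyp
            else:
                feats = arch.compute_epoch_features(
                    rec, spec.epoch_length_s, a.get("eeg_channel", "EEG1")
                )
                hyp = arch.score_epochs(feats)
            summary = arch.summarize_architecture(
                hyp, block_hours=float(a.get("block_hours", 12.0))
            )
            arch_rows.append(summary.to_frame(rec.subject_id, group))

            for state in STATES:
                segments = signal_io.export_state_segments(
                    rec, hyp, state, a.get("eeg_channel", "EEG1")
                )
                try:
                    x = prep.standardize_state(
                        segments, state, rec.sampling_rate_hz, std_spec
                    )
                except ShortfallError as e:
                    log.warning("excluding %s/%s: %s", rec.subject_id, state, e)
                    exclusions.append(
                        {"subject": rec.subject_id, "state": state, "reason": str(e)}
                    )
                    continue
                psd = spectral.welch_psd(
                    x, rec.sampling_rate_hz, state=state, subject_id=rec.subject_id
                )
                for f, d in zip(psd.frequencies_hz, psd.density):
                    psd_rows.append((rec.subject_id, group, state, f, d))
                for band in bands:
                    band_rows.append(
                        (
                            rec.subject_id,
                            group,
                            state,
                            band.name,
                            spectral.band_power(psd, band),
                        )
                    )
                series = pacmod.phase_amplitude_series(
                    x,
                    rec.sampling_rate_hz,
                    tuple(pac_cfg["phase_band"]),
                    tuple(pac_cfg["amp_band"]),
                )
                res = pacmod.mi_canolty(series)
                null = pacmod.surrogate_test(
                    series,
                    method=pac_cfg.get("method", "canolty"),
                    n_surrogates=int(pac_cfg.get("n_surrogates", 100)),
                    scheme=pac_cfg.get("scheme", "circular_shift"),
                    seed=_subject_seed(master, 7, gi, si, STATES.index(state)),
                )
                pac_rows.append(
                    (
                        rec.subject_id,
                        group,
                        state,
                        pac_cfg.get("method", "canolty"),
                        res.mi_canolty,
                        res.mi_normalized,
                        res.mean_vector_angle,
                        null.p,
                    )
                )

    tables = {
        "architecture": pd.concat(arch_rows, ignore_index=True)
        if arch_rows
        else pd.DataFrame(),
        "band_power": pd.DataFrame(
            band_rows, columns=["subject", "group", "state", "band", "power_uv2"]
        ),
        "psd": pd.DataFrame(
            psd_rows, columns=["subject", "group", "state", "frequency_hz", "density"]
        ),
        "pac": pd.DataFrame(
            pac_rows,
            columns=[
                "subject", "group", "state", "method",
                "mi_canolty", "mi_normalized", "mean_vector_angle_rad", "p_surrogate",
            ],
        ),
    }
    tables["comparisons"] = _compare(tables)

    for name, df in tables.items():
        df.to_csv(os.path.join(out_dir, f"{name}.csv"), index=False)
    _write_manifest(config, out_dir, exclusions)
    return tables


def _metric_groups(df: pd.DataFrame, value_col: str) -> dict[str, np.ndarray]:
    return {
        g: sub[value_col].to_numpy(dtype=float) for g, sub in df.groupby("group", sort=False)
    }


def _compare(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    rows = []

    def add(metric: str, groups: dict[str, np.ndarray]) -> None:
        sizes = [v.size for v in groups.values()]
        if len(groups) < 2 or min(sizes) < 2:
            return
        try:
            cmp_res = gstats.compare_groups(groups, metric=metric)
        except ValidationError:
            return
        rows.append(
            {
                "metric": metric,
                "test": cmp_res.test,
                "gate": cmp_res.gate,
                "statistic": cmp_res.statistic,
                "p": cmp_res.p,
            }
        )

    bp = tables["band_power"]
    for (state, band), sub in bp.groupby(["state", "band"], sort=False):
        add(f"band_power:{state}:{band}", _metric_groups(sub, "power_uv2"))
    pc = tables["pac"]
    for state, sub in pc.groupby("state", sort=False):
        add(f"pac_mi:{state}", _metric_groups(sub, "mi_canolty"))
    ar = tables["architecture"]
    if not ar.empty:
        for (label, state, metric), sub in ar.groupby(
            ["block_label", "state", "metric"], sort=False
        ):
            per_subject = sub.groupby(["subject", "group"], sort=False)["value"].mean().reset_index()
            add(
                f"architecture:{label}:{state}:{metric}",
                _metric_groups(per_subject, "value"),
            )

    df = pd.DataFrame(rows)
    if not df.empty:
        reject, adjusted = gstats.holm_bonferroni(df["p"].to_numpy())
        df["p_holm"] = adjusted
        df["significant"] = reject
    return df


def _write_manifest(config: dict, out_dir: str, exclusions: list[dict]) -> None:
    try:
        pkg_version = version("somnopac")
    except PackageNotFoundError:  # pragma: no cover
        pkg_version = "unknown"
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": config.get("seed", 0),
        "package_version": pkg_version,
        "excluded": exclusions,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
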