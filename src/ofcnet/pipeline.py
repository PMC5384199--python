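"""End-to-end orchestration: filter → epoch → correlate → quarter → dissimilarity.

`subject_analysis` runs the per-animal LFP analysis; `run_pipeline` drives
whole simulated cohorts through it, scores behavior, quantifies the
plaque–freezing statistics, and writes every table with the effective
configuration echoed next to it (config hash + seed), so a run can be
reproduced byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stats as ofstats
from .behavior import exclude_outliers, score_freezing
from .connectivity import (
    ConnectivityMatrix,
    dissimilarity_trajectory,
    group_matrix,
    subject_matrix,
)
from .io import Recording
from .protocol import (
    EpochSet,
    SessionProtocol,
    conditioning_epochs,
    habituation_epochs,
    quarter_partition,
)
from .spectral import THETA, BandTable, band_powers, psd
from .synth import GroupSpec, generate_group_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "subject_analysis", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on; round-trips through YAML."""

    protocol: SessionProtocol = field(default_factory=SessionProtocol)
    band: tuple[float, float] = THETA
    mode: str = "zero-lag"
    fisher_mean: bool = False
    seed: int = 0
    groups: tuple[GroupSpec, ...] = field(
        default_factory=lambda: (GroupSpec(), GroupSpec.wildtype())
    )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return _plain(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            protocol=SessionProtocol(**d["protocol"]),
            band=tuple(d["band"]),
            mode=d["mode"],
            fisher_mean=d["fisher_mean"],
            seed=d["seed"],
            groups=tuple(
                GroupSpec(
                    **{
                        k: tuple(v) if isinstance(v, list) else v
                        for k, v in g.items()
                    }
                )
                for g in d["groups"]
            ),
        )

    def hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def subject_analysis(
    rec: Recording,
    protocol: SessionProtocol,
    band: tuple[float, float] = THETA,
    mode: str = "zero-lag",
    fisher_mean: bool = False,
    bands: BandTable | None = None,
    compute_band_power: bool = True,
) -> dict:
    """Per-animal LFP analysis.

    Guard-trimmed conditioning epochs and habituation tiles are sliced from
    the raw recording and band-filtered per epoch; connectivity matrices are
    built for habituation, the full conditioning phase, and each of the four
    conditioning quarters, then the quartered dissimilarity trajectory from
    the habituation matrix is computed.  Normalized band-power tables are
    estimated per phase from the same epochs.
    """
    hab = habituation_epochs(protocol)
    cond = conditioning_epochs(protocol)
    quarters = quarter_partition(protocol, cond)

    kw = dict(band=band, mode=mode, fisher_mean=fisher_mean)
    hab_mat = subject_matrix(rec, hab, **kw)
    cond_mat = subject_matrix(rec, cond, **kw)
    quarter_mats = [subject_matrix(rec, q, **kw) for q in quarters]
    trajectory = dissimilarity_trajectory(hab_mat, quarter_mats)

    power_table = None
    if compute_band_power:
        bands = bands or BandTable.default()
        power_rows = []
        for phase_name, eps in (("habituation", hab), ("conditioning", cond)):
            stack = np.stack([rec.samples[:, sl] for sl in eps.sample_slices(rec.fs)])
            freqs, pxx = psd(stack, rec.fs)
            for ch, label in enumerate(rec.labels):
                series, _ = band_powers(freqs, pxx[ch], bands)
                for bname, value in series.items():
                    power_rows.append((label, phase_name, bname, value))
        power_table = pd.DataFrame(
            power_rows, columns=["channel", "phase", "band", "normalized_power"]
        )

    return {
        "habituation_matrix": hab_mat,
        "conditioning_matrix": cond_mat,
        "quarter_matrices": quarter_mats,
        "trajectory": trajectory,
        "band_power": power_table,
        "epochs": {"habituation": hab, "conditioning": cond},
    }


def run_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Simulate the configured cohorts and run the full analysis.

    Returns a result bundle keyed by group name with per-subject and group
    matrices, trajectories, freezing summaries (with >2-SD exclusion flags),
    plaque tables, and the cross-group statistics; optionally writes every
    table under ``out_dir`` tagged with the config hash and seed.
    """
    bundle: dict = {"config": config.to_dict(), "config_hash": config.hash(), "groups": {}}
    traj_by_group: dict[str, np.ndarray] = {}

    for spec in config.groups:
        data = generate_group_dataset(spec, protocol=config.protocol, seed=config.seed)
        per_subject = []
        freezing_totals = []
        plaque_rows = []
        for sub in data["subjects"]:
            res = subject_analysis(
                sub["recording"], config.protocol, band=config.band,
                mode=config.mode, fisher_mean=config.fisher_mean,
            )
            res["id"] = sub["id"]
            cond_slice = slice(
                int(config.protocol.conditioning_start * sub["trace"].fs),
                int(config.protocol.total_duration * sub["trace"].fs),
            )
            cond_trace = type(sub["trace"])(
                immobile=sub["trace"].immobile[cond_slice],
                fs=sub["trace"].fs,
                phase="conditioning",
            )
            res["freezing"] = score_freezing(cond_trace)
            freezing_totals.append(res["freezing"].total)
            for region, burden in sub["plaque_burden"].items():
                plaque_rows.append((sub["id"], region, burden))
            per_subject.append(res)

        mask = (
            exclude_outliers(np.asarray(freezing_totals))
            if len(freezing_totals) >= 3
            else np.ones(len(freezing_totals), dtype=bool)
        )
        for res, keep in zip(per_subject, mask):
            res["freezing"] = dataclasses.replace(res["freezing"], excluded=not keep)

        hab_group, hab_pairs = group_matrix([r["habituation_matrix"] for r in per_subject])
        cond_group, cond_pairs = group_matrix([r["conditioning_matrix"] for r in per_subject])
        mean_traj = np.mean([r["trajectory"].values for r in per_subject], axis=0)
        traj_by_group[spec.name] = mean_traj

        bundle["groups"][spec.name] = {
            "subjects": per_subject,
            "habituation_matrix": hab_group,
            "conditioning_matrix": cond_group,
            "pair_values": {"habituation": hab_pairs, "conditioning": cond_pairs},
            "mean_trajectory": mean_traj,
            "freezing_totals": np.asarray(freezing_totals),
            "included": mask,
            "plaque": pd.DataFrame(plaque_rows, columns=["animal", "region", "burden"]),
        }

    bundle["stats"] = _cross_group_stats(bundle, traj_by_group)
    if out_dir is not None:
        _write_bundle(bundle, config, Path(out_dir))
    return bundle


def _cross_group_stats(bundle: dict, traj_by_group: dict) -> dict:
    out: dict = {}
    names = list(traj_by_group)
    if len(names) == 2:
        a, b = (traj_by_group[n] for n in names)
        res = ofstats.pearson(a, b)
        out["trajectory_correlation"] = {
            "groups": names, "r": res.coefficient, "p": res.p_value, "n": res.n,
        }
    for name, g in bundle["groups"].items():
        plaque = g["plaque"]
        freeze = pd.Series(
            g["freezing_totals"], index=[r["id"] for r in g["subjects"]]
        )
        region_rs = {}
        for region, sub in plaque.groupby("region"):
            burdens = sub.set_index("animal")["burden"].reindex(freeze.index)
            if burdens.nunique() < 2 or freeze.nunique() < 2 or len(freeze) < 3:
                continue
            res = ofstats.spearman(burdens.to_numpy(), freeze.to_numpy())
            region_rs[region] = {"r_s": res.coefficient, "p": res.p_value, "n": res.n}
        if region_rs:
            out.setdefault("plaque_freezing", {})[name] = region_rs
    return out


def _write_bundle(bundle: dict, config: RunConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config.yaml")
    meta = {"config_hash": bundle["config_hash"], "seed": config.seed}
    (out_dir / "run.json").write_text(json.dumps(meta, indent=2))
    for name, g in bundle["groups"].items():
        gdir = out_dir / name
        gdir.mkdir(exist_ok=True)
        g["habituation_matrix"].write(gdir / "habituation_matrix.tsv",
                                      gdir / "habituation_matrix.json")
        g["conditioning_matrix"].write(gdir / "conditioning_matrix.tsv",
                                       gdir / "conditioning_matrix.json")
        g["pair_values"]["conditioning"].to_csv(gdir / "pair_values_conditioning.csv",
                                                index=False)
        pd.DataFrame(
            {
                "quarter": np.arange(1, len(g["mean_trajectory"]) + 1),
                "dissimilarity": g["mean_trajectory"],
            }
        ).to_csv(gdir / "trajectory.csv", index=False)
        g["plaque"].to_csv(gdir / "plaque.csv", index=False)
        freezing = pd.DataFrame(
            {
                "animal": [r["id"] for r in g["subjects"]],
                "freezing_s": g["freezing_totals"],
                "included": g["included"],
            }
        )
        freezing.to_csv(gdir / "freezing.csv", index=False)
        for r in g["subjects"]:
            r["band_power"].to_csv(gdir / f"band_power_{r['id']}.csv", index=False)
    (out_dir / "stats.json").write_text(json.dumps(_plain(bundle["stats"]), indent=2))
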