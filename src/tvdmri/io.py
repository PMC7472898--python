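"""Readers/writers, run configuration and the end-to-end pipeline.

Signal volumes travel as 4-D NIfTI-1 plus an FSL-style bval/bvec pair
and a one-column shape-label sidecar; masks as uint8 NIfTI; cohort
tables as TSV.  ``run_pipeline`` composes the stages (cohort simulation
-> per-subject phantom and signals -> FA and uFA maps -> ROI means ->
group/correlation statistics) deterministically from one master seed,
with per-stage and per-subject streams split by counter.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import cohort as coh
from .cohort import EffectConfig, simulate_cohort, subject_phantom, cohort_dataframe
from .dti import fit_dti, ScalarMap
from .encoding import Protocol, multishell_protocol, tensor_valued_protocol
from .gamma import ufa_map
from .phantom import SignalVolume, add_rician_noise, simulate_signal
from .stats import correlate, rm_anova, roi_mean

__all__ = [
    "RunConfig",
    "read_signal_dataset",
    "write_signal_dataset",
    "read_mask",
    "write_mask",
    "write_scalar_map",
    "run_pipeline",
]

log = logging.getLogger("tvdmri")


def write_signal_dataset(volume: SignalVolume, nifti_path: str | Path,
                         sidecar_prefix: str | Path | None = None) -> None:
    nifti_path = Path(nifti_path)
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    img.header.set_zooms(tuple(volume.voxel_size) + (1.0,))
    nib.save(img, str(nifti_path))
    if sidecar_prefix is None:
        sidecar_prefix = nifti_path.parent / nifti_path.name.split(".")[0]
    volume.protocol.to_fsl(sidecar_prefix)


def read_signal_dataset(nifti_path: str | Path,
                        sidecar_prefix: str | Path | None = None) -> SignalVolume:
    """Read a 4-D NIfTI (plain or gz) with its bval/bvec/shapes sidecar."""
    nifti_path = Path(nifti_path)
    if sidecar_prefix is None:
        sidecar_prefix = nifti_path.parent / nifti_path.name.split(".")[0]
    img = nib.load(str(nifti_path))
    affine = img.affine
    if not np.all(np.isfinite(affine)):
        raise ValueError("non-finite affine in NIfTI header")
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4-D signal volume")
    protocol = Protocol.from_fsl(sidecar_prefix)
    if len(protocol) != data.shape[3]:
        raise ValueError(
            f"protocol length {len(protocol)} does not match 4th dimension {data.shape[3]}"
        )
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return SignalVolume(data, protocol, voxel_size, affine)


def write_mask(mask: np.ndarray, path: str | Path, voxel_size=(2.5, 2.5, 2.5)) -> None:
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def read_mask(path: str | Path) -> np.ndarray:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"mask file not found: {p}")
    return np.asarray(nib.load(str(p)).dataobj) > 0


def write_scalar_map(smap: ScalarMap, path: str | Path) -> None:
    data = np.where(smap.mask, smap.data, np.nan).astype(np.float32)
    nib.save(nib.Nifti1Image(data, smap.affine), str(path))


@dataclass
class RunConfig:
    """Fully serialisable description of one pipeline run."""

    seed: int = 0
    n_hc: int = 27
    n_rrms: int = 26
    n_ppms: int = 14
    snr: float = 50.0
    fwhm_mm: float = 1.25
    phantom_shape: tuple[int, int, int] = (8, 4, 1)
    n_lte_dirs: int = 15
    n_ste_reps: int = 15
    fa_thresholds: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6)
    histogram_bins: int = 64
    effect_config: dict = field(default_factory=lambda: asdict(EffectConfig()))
    out_dir: str | None = None

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "phantom_shape" in raw:
            raw["phantom_shape"] = tuple(raw["phantom_shape"])
        if "fa_thresholds" in raw:
            raw["fa_thresholds"] = tuple(raw["fa_thresholds"])
        return cls(**raw)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _subject_seed(master: int, index: int, stream: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=(stream, index))
    return int(ss.generate_state(1)[0] % (2**31))


def subject_maps(subject, config: RunConfig, index: int, master_seed: int):
    """Simulate one subject's volumes and fit FA and uFA maps."""
    phantom = subject_phantom(
        subject, shape=tuple(config.phantom_shape),
        seed=_subject_seed(master_seed, index, 1),
    )
    tv_prot = tensor_valued_protocol(config.n_lte_dirs, config.n_ste_reps,
                                     seed=master_seed % 10_000)
    ms_prot = multishell_protocol(seed=master_seed % 10_000)
    tv = simulate_signal(phantom, tv_prot)
    ms = simulate_signal(phantom, ms_prot)
    if np.isfinite(config.snr):
        tv = add_rician_noise(tv, config.snr, _subject_seed(master_seed, index, 2))
        ms = add_rician_noise(ms, config.snr, _subject_seed(master_seed, index, 3))
    fa = fit_dti(ms, phantom.masks["NAWM"] | phantom.masks["lesions"]).fa_map()
    ufa, qc = ufa_map(tv, phantom.masks["NAWM"] | phantom.masks["lesions"],
                      fwhm_mm=config.fwhm_mm)
    return phantom, fa, ufa, qc


def pipeline_roi_table(config: RunConfig, subjects=None) -> pd.DataFrame:
    """Image-based per-subject ROI table (full simulate-fit-measure path)."""
    cfg = EffectConfig(**config.effect_config)
    if subjects is None:
        subjects = simulate_cohort(config.n_hc, config.n_rrms, config.n_ppms,
                                   cfg, seed=config.seed)
    rows = []
    nx = config.phantom_shape[0]
    for i, s in enumerate(subjects):
        phantom, fa, ufa, _ = subject_maps(s, config, i, config.seed)
        hemi_sel = {
            "left": np.arange(nx) < nx // 2,
            "right": np.arange(nx) >= nx // 2,
        }
        for hemi, xs in hemi_sel.items():
            hemi_mask = np.zeros(phantom.shape, dtype=bool)
            hemi_mask[xs] = True
            rois = {"NAWM": phantom.masks["NAWM"] & hemi_mask}
            for tract in ("CING", "SLF", "CST"):
                rois[tract] = phantom.masks[f"{tract}_{hemi}"]
            for roi, m in rois.items():
                base = {
                    "id": s.id, "group": s.group, "age": s.age, "sex": s.sex,
                    "edss": s.edss, "sdmt": s.sdmt,
                    "lesion_load_ml": s.lesion_load_ml,
                    "roi": roi, "hemisphere": hemi,
                }
                row = dict(base)
                row["FA"] = roi_mean(fa, m, roi, s.id, hemi).mean
                row["uFA"] = roi_mean(ufa, m, roi, s.id, hemi).mean
                row["n_voxels"] = int(m.sum())
                rows.append(row)
    return pd.DataFrame(rows)


def _correlation_block(df: pd.DataFrame, metric: str) -> list[dict]:
    """The clinical correlations of one metric's NAWM hemisphere means."""
    out = []
    nawm = df[df["roi"] == "NAWM"]
    for hemi in ("left", "right"):
        sub = nawm[nawm["hemisphere"] == hemi]
        patients = sub[sub["group"] != "HC"]
        pairs = [
            ("age_all", sub["age"], sub[metric], "pearson", None),
            ("edss_patients", patients["edss"], patients[metric], "pearson", None),
            ("sdmt_patients", patients["sdmt"], patients[metric], "pearson", None),
            ("lesion_load_patients", patients["lesion_load_ml"], patients[metric],
             "spearman", None),
            ("edss_patients_age_adj", patients["edss"], patients[metric],
             "partial_pearson", patients["age"]),
        ]
        for name, x, y, method, ctl in pairs:
            try:
                res = correlate(x, y, method=method, control=ctl)
                out.append({"metric": metric, "hemisphere": hemi, "variable": name,
                            "method": res.method, "r": res.r, "p": res.p, "n": res.n})
            except ValueError as exc:
                out.append({"metric": metric, "hemisphere": hemi, "variable": name,
                            "method": method, "r": np.nan, "p": np.nan,
                            "n": 0, "note": str(exc)})
    return out


def run_pipeline(config: RunConfig, fast: bool = False) -> dict:
    """Run the full analysis and return a JSON-serialisable report.

    ``fast=True`` swaps the image-based ROI table for the generator's
    closed-form path (identical schema, no voxelwise fitting).
    """
    cfg = EffectConfig(**config.effect_config)
    subjects = simulate_cohort(config.n_hc, config.n_rrms, config.n_ppms,
                               cfg, seed=config.seed)
    n_subjects = len(subjects)
    log.info("pipeline: %d subjects, seed %d, config %s",
             n_subjects, config.seed, config.hash())
    if fast:
        table = coh.closed_form_roi_table(subjects, cfg, seed=config.seed)
    else:
        table = pipeline_roi_table(config, subjects)
    report: dict = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_subjects": n_subjects,
        "underpowered": n_subjects < 12,
        "anova": {},
        "correlations": [],
    }
    for metric in ("FA", "uFA"):
        try:
            res = rm_anova(table, metric, roi="NAWM")
        except Exception as exc:  # statistics failures are reported, not fatal
            report["anova"][metric] = {"error": str(exc)}
            continue
        report["anova"][metric] = {
            name: {
                "F": r.F, "df": list(r.df), "p": r.p,
                **({"pairwise": r.pairwise.to_dict("records")} if r.pairwise is not None else {}),
            }
            for name, r in res.items()
        }
        report["correlations"] += _correlation_block(table, metric)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cohort_dataframe(subjects).to_csv(out / "cohort.tsv", sep="\t", index=False)
        table.to_csv(out / "roi_means.tsv", sep="\t", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
        config.to_yaml(out / "config.yaml")
    return report
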