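"""End-to-end driver: simulate -> GLM -> decode -> group -> behaviour.

The pipeline runs entirely in memory on the synthetic cohort and returns a
JSON-serialisable report; optional ``out_dir`` persists accuracy maps,
statistic maps, peak tables and a provenance sidecar.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import behavior as bh
from . import group as grp
from . import searchlight as sl
from .design import DesignSpec
from .glm import TrialBetaGLM
from .phantom import CohortSpec, PhantomSpec, simulate_cohort


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, with per-stage seeds.

    Defaults reproduce the study conditions (4 runs x 36 trials, 3
    speakers, 12-mm searchlight, C = 1 linear OvO SVM, chance 1/3, 8-mm
    smoothing) at a phantom grid small enough for desktop runs.
    """

    n_subjects: int = 12
    coupling: float = 1.0
    grid_shape: tuple = (12, 12, 10)
    noise_sigma: float = 0.5
    effect_scale: float = 1.0
    radius_mm: float = 12.0
    kernel: str = "linear"
    C: float = 1.0
    fwhm_mm: float = 8.0
    n_permutations: int = 1000
    alpha: float = 0.05
    chance: float = 1.0 / 3.0
    run_searchlight: bool = True
    seed: int = 0

    def seeds(self):
        ss = np.random.SeedSequence(self.seed)
        kids = ss.spawn(3)
        return {
            "cohort": int(kids[0].generate_state(1)[0] % (2**31)),
            "signflip": int(kids[1].generate_state(1)[0] % (2**31)),
            "regression": int(kids[2].generate_state(1)[0] % (2**31)),
        }


def run_pipeline(config: PipelineConfig | dict | None = None,
                 out_dir=None) -> dict:
    """Run the full analysis on a synthetic cohort; return the report."""
    if config is None:
        config = PipelineConfig()
    elif isinstance(config, dict):
        config = PipelineConfig(**config)
    seeds = config.seeds()

    design_spec = DesignSpec()
    phantom = PhantomSpec(grid_shape=tuple(config.grid_shape),
                          noise_sigma=config.noise_sigma)
    cohort = CohortSpec(n_subjects=config.n_subjects,
                        coupling=config.coupling, seed=seeds["cohort"])
    roi = phantom.informative_mask()
    sound_mask = phantom.sound_responsive_mask

    acc_maps, roi_loro, roi_lowo, pcs, subjects = [], [], [], [], []
    roi_confusions = []
    abilities, effects = [], []
    for data in simulate_cohort(cohort, design_spec, phantom,
                                effect_scale=config.effect_scale):
        betas = None
        for run_id, run_vol in enumerate(data["runs"], start=1):
            ev = data["events"]
            ev_run = ev[ev["run"] == run_id]
            est = TrialBetaGLM().fit(run_vol, ev_run, design_spec.tr,
                                     voxel_size=phantom.voxel_size_mm)
            bs = est.beta_series_
            betas = bs if betas is None else betas.concat(bs)
        if config.run_searchlight:
            acc_maps.append(
                sl.run_searchlight(betas, mask=sound_mask,
                                   radius_mm=config.radius_mm,
                                   scheme="loro", kernel=config.kernel,
                                   C=config.C)
            )
        a_loro, cm_loro = sl.roi_accuracy(betas, roi, scheme="loro",
                                          kernel=config.kernel, C=config.C)
        a_lowo, _ = sl.roi_accuracy(betas, roi, scheme="lowo",
                                    kernel=config.kernel, C=config.C)
        roi_loro.append(a_loro)
        roi_lowo.append(a_lowo)
        roi_confusions.append(cm_loro.cells)
        summary = bh.percent_correct(data["events"])
        pcs.append(summary.pc_overall)
        abilities.append(data["ability"])
        effects.append(data["subject_effect"])
        subjects.append(data["subject"])

    pcs = np.asarray(pcs)
    roi_loro = np.asarray(roi_loro)
    roi_lowo = np.asarray(roi_lowo)

    report = {
        "n_subjects": config.n_subjects,
        "behavior": {
            "mean_pc": float(pcs.mean()),
            "sd_pc": float(pcs.std(ddof=1)),
        },
        "roi": {
            "mean_accuracy_loro": float(roi_loro.mean()),
            "mean_accuracy_lowo": float(roi_lowo.mean()),
        },
    }
    t_chance, p_chance = sl.one_sample_vs_chance(100 * roi_loro,
                                                 chance=100 * config.chance)
    t_pair, p_pair = sl.scheme_comparison(roi_loro, roi_lowo)
    report["roi"]["t_vs_chance_loro"] = t_chance
    report["roi"]["p_vs_chance_loro"] = p_chance
    report["roi"]["paired_t_loro_vs_lowo"] = t_pair
    report["roi"]["paired_p_loro_vs_lowo"] = p_pair

    rho, rho_p = stats.spearmanr(roi_loro, pcs)
    report["brain_behavior"] = {
        "spearman_rho_roi_vs_pc": float(rho),
        "one_tailed_p": float(rho_p / 2 if rho > 0 else 1 - rho_p / 2),
        "true_ability_vs_effect_r": float(np.corrcoef(abilities, effects)[0, 1]),
    }

    group_section = {}
    if config.run_searchlight and len(acc_maps) >= 2:
        maps = []
        for m in acc_maps:
            centered = grp.subtract_chance(m, config.chance)
            maps.append(grp.gaussian_smooth(centered, config.fwhm_mm,
                                            phantom.voxel_size_mm,
                                            mask=sound_mask))
        maps = np.asarray(maps)
        res = grp.signflip_onesample(maps, config.n_permutations,
                                     seed=seeds["signflip"],
                                     mask=sound_mask, alpha=config.alpha)
        sig = res.significant()
        peaks = grp.cluster_peaks(
            np.where(sig, res.stat, np.nan), threshold=-np.inf,
            voxel_size_mm=phantom.voxel_size_mm,
            min_cluster_mm3=20.0, min_peak_separation_mm=8.0,
        )
        reg = grp.permutation_regression(maps, pcs, config.n_permutations,
                                         seed=seeds["regression"],
                                         mask=sound_mask, alpha=config.alpha)
        n_roi_sig = int(sig[roi].sum())
        group_section = {
            "n_significant_voxels": int(sig.sum()),
            "n_significant_in_informative_roi": n_roi_sig,
            "min_p_fwe": float(np.nanmin(res.p_fwe)),
            "regression_min_p_fwe": float(np.nanmin(reg.p_fwe)),
            "n_peaks": int(len(peaks)),
        }
        report["group"] = group_section

    report["subjects"] = {
        "id": subjects,
        "pc": pcs.tolist(),
        "roi_accuracy_loro": roi_loro.tolist(),
        "roi_accuracy_lowo": roi_lowo.tolist(),
        "true_ability": [float(a) for a in abilities],
    }

    if out_dir is not None:
        from .io import save_config, write_sidecar

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, default=str)
        )
        cfg = asdict(config)
        save_config(cfg, out_dir / "config.json")
        write_sidecar(out_dir / "report.json", cfg, seeds=seeds)
    return report
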