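"""End-to-end workflow wiring with provenance.

``run_pipeline`` executes simulate -> preprocess -> discover -> evaluate
-> prognose on a config, writing every artifact plus a manifest of
checksums.  Stage seeds derive deterministically from the master seed and
the stage name, so a re-run with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .benchmark import mean_z_score
from .diagnostics import repeated_cv_auc
from .discovery import DiscoveryConfig, differential_abundance, run_funnel, down_select_panel
from .matrix import write_matrix
from .preprocess import PreprocessConfig, preprocess
from .prognosis import build_transition_dataset, cox_fit
from .signatures import save_signature
from .simulate import SimProgressionConfig, SimStudyConfig, simulate_cohort, simulate_multi_study

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "stage_seed", "run_pipeline", "default_config"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a stage seed: low 31 bits of sha256(master_seed:stage)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    out_dir: Path
    master_seed: int = 0
    n_studies: int = 4
    n_proteins: int = 200
    n_per_arm: int = 30
    n_shared_markers: int = 12
    shared_effect: float = 1.0
    noise_sd: float = 0.4
    study_specific_hits: int = 3
    concordance: float = 1.0
    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    progression_n: int = 300
    progression_hr: float = 3.0

    @classmethod
    def from_yaml(cls, path, out_dir=None, master_seed=None) -> "RunConfig":
        with open(path) as fh:
            blob = yaml.safe_load(fh) or {}
        disc = DiscoveryConfig(**blob.pop("discovery", {}))
        prep = PreprocessConfig(**blob.pop("preprocessing", {}))
        if out_dir is not None:
            blob["out_dir"] = out_dir
        if master_seed is not None:
            blob["master_seed"] = master_seed
        return cls(discovery=disc, preprocessing=prep, **blob)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def default_config(out_dir, master_seed: int = 0) -> RunConfig:
    return RunConfig(out_dir=Path(out_dir), master_seed=master_seed)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the synthetic end-to-end workflow; returns the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {
        "version": __version__,
        "master_seed": cfg.master_seed,
        "stage_seeds": {s: stage_seed(cfg.master_seed, s)
                        for s in ("simulate", "discover", "evaluate", "prognose")},
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    artifacts = []

    # -- simulate ------------------------------------------------------
    sim_seed = stage_seed(cfg.master_seed, "simulate")
    shared = [(f"MK{i:03d}", cfg.shared_effect * (1 if i % 2 == 0 else -1))
              for i in range(cfg.n_shared_markers)]
    configs = [
        SimStudyConfig(
            cohort_id=f"study{j}", n_case=cfg.n_per_arm, n_control=cfg.n_per_arm,
            n_proteins=cfg.n_proteins, seed=sim_seed + j, noise_sd=cfg.noise_sd,
            study_specific_hits=cfg.study_specific_hits,
            platform_offset=0.5 * j, platform_gain=1.0 + 0.05 * j)
        for j in range(cfg.n_studies)
    ]
    bundles, truth = simulate_multi_study(configs, shared, cfg.concordance, seed=sim_seed)
    for m, subjects, _ in bundles:
        p = out / f"{m.cohort_id}_matrix.tsv"
        write_matrix(m, p)
        artifacts.append(p)
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(
        {"shared": [g for g, _ in shared],
         "flipped": truth.attrs.get("flipped", {})}, indent=2))
    artifacts.append(truth_path)

    # -- preprocess + discover ----------------------------------------
    processed = [preprocess(m, cfg.preprocessing) for m, _, _ in bundles]
    labels = [{s.subject_id: ("case" if s.is_at_positive else "control")
               for s in subjects} for _, subjects, _ in bundles]
    per_study = {m.cohort_id: differential_abundance(m, lab, cfg.discovery)
                 for m, lab in zip(processed, labels)}
    funnel = run_funnel(per_study, processed, cfg.discovery)
    counts = {"daps": funnel["n_daps"], "shared": len(funnel["shared"]),
              "concordant": len(funnel["concordant"]),
              "candidates": len(funnel["candidates"])}
    candidates = [t.gene_symbol for t in funnel["candidates"]]
    disc_seed = stage_seed(cfg.master_seed, "discover")
    if len(candidates) >= 2:
        sig = down_select_panel(candidates, list(zip(processed, labels)),
                                cfg.discovery, seed=disc_seed, name="sim_panel")
    else:
        from .signatures import Signature
        sig = Signature(name="sim_panel", gene_symbols=candidates or ["MK000"])
    sig_path = out / "signature.json"
    save_signature(sig, sig_path)
    artifacts.append(sig_path)
    funnel_path = out / "funnel_counts.json"
    funnel_path.write_text(json.dumps(counts, indent=2))
    artifacts.append(funnel_path)

    # -- evaluate ------------------------------------------------------
    eval_seed = stage_seed(cfg.master_seed, "evaluate")
    diag = repeated_cv_auc(processed[0], labels[0], sig, seed=eval_seed,
                           comparison="A+T+ vs A-T-")
    diag_path = out / "diagnostic_result.json"
    diag_path.write_text(json.dumps(diag.to_dict(), indent=2))
    artifacts.append(diag_path)

    # -- prognose ------------------------------------------------------
    prog_seed = stage_seed(cfg.master_seed, "prognose")
    from .simulate import simulate_progression_cohort
    records = simulate_progression_cohort(SimProgressionConfig(
        n_subjects=cfg.progression_n, hazard_ratio_true=cfg.progression_hr,
        seed=prog_seed))
    hz = cox_fit(records, covariates=("age", "sex"), transition="simulated")
    hz_path = out / "hazard_result.json"
    hz_path.write_text(json.dumps(hz.to_dict(), indent=2))
    artifacts.append(hz_path)

    manifest = {
        "artifacts": {str(p.relative_to(out)): _sha256(p) for p in sorted(artifacts)},
        "funnel_counts": counts,
        "signature": sig.gene_symbols,
        "cv_auc": diag.auc,
        "hazard_ratio": hz.hr,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
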