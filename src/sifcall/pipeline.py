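"""One-shot pipeline: QC -> mixture fit -> background filter -> calling -> merge."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import background as bg
from . import calling, contacts
from .fragments import FragmentMap
from .mixture import PoissonMixture, bootstrap_fit

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All pipeline tunables with their documented defaults."""

    ftr: int = 1
    fdr_threshold: float = 0.1
    n_resample: int = 100_000          # Np draws for the empirical null
    efficiency: float = 0.7            # digestion efficiency E
    half_width: int = 5                # neighbor window K
    background_threshold: float | None = None   # None = data-adaptive
    n_boot: int = 50                   # bootstrap rounds; 0 disables
    em_tol: float = 1e-6
    em_max_iter: int = 1000
    d_min: float = 1e3                 # power-law fit range
    d_max: float = 1e8
    intra_only: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in names})

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def run_pipeline(pairs: pd.DataFrame, fmap: FragmentMap,
                 config: RunConfig | None = None) -> tuple[list, dict]:
    """Run the full calling pipeline on a read-pair table.

    Stages: deduplicate and classify ligation products; tally valid pairs
    into USF records; fit the two-component Poisson mixture (bootstrapped);
    fit the power-law distance decay and remove linear-closeness background;
    build the FDR table from the filtered records; apply the FTR and local
    FDR gates; merge equal-score adjacent calls.

    Returns ``(sifs, report)`` where the report carries per-stage counts and
    every fitted parameter.
    """
    cfg = config or RunConfig()
    report: dict = {"config": cfg.to_dict(), "config_hash": cfg.digest(), "stages": {}}

    # --- QC
    dedup = contacts.deduplicate_pairs(pairs)
    classes = contacts.classify_pairs(dedup, fmap)
    valid = dedup[classes == contacts.VALID].reset_index(drop=True)
    report["stages"]["qc"] = {
        "total": len(pairs), "deduplicated": len(dedup),
        "self_ligation": int((classes == contacts.SELF_LIGATION).sum()),
        "re_ligation": int((classes == contacts.RE_LIGATION).sum()),
        "valid": len(valid),
    }
    if len(valid) == 0:
        raise RuntimeError("stage qc: no valid ligation pairs")

    # --- USF table
    records = contacts.build_usf_table(valid, fmap, intra_only=cfg.intra_only,
                                       deduplicate=False)
    report["stages"]["usf"] = {"records": len(records),
                               "reads": int(records["score"].sum())}
    if len(records) == 0:
        raise RuntimeError("stage usf: no records")

    # --- mixture fit
    scores = records["score"].to_numpy()
    try:
        if cfg.n_boot >= 2:
            model = bootstrap_fit(scores, n_boot=cfg.n_boot, seed=cfg.seed,
                                  tol=cfg.em_tol, max_iter=cfg.em_max_iter)
        else:
            model = PoissonMixture(tol=cfg.em_tol, max_iter=cfg.em_max_iter).fit(scores)
    except ValueError as exc:
        raise RuntimeError(f"stage fit: {exc}") from exc
    report["stages"]["fit"] = model.to_dict()

    # --- background power law + digestion-efficiency filter
    try:
        profile = contacts.distance_profile(valid, d_min=cfg.d_min)
        plaw = bg.fit_power_law(profile, d_min=cfg.d_min, d_max=cfg.d_max)
        bcfg = bg.BackgroundConfig(efficiency=cfg.efficiency,
                                   half_width=cfg.half_width,
                                   threshold=cfg.background_threshold)
        filtered, removed, info = bg.filter_background(records, fmap, bcfg, plaw)
        report["stages"]["background"] = {**plaw.to_dict(), **info}
    except ValueError as exc:
        raise RuntimeError(f"stage background: {exc}") from exc

    # --- FDR table and calling
    try:
        table = calling.build_fdr_table(filtered["score"].to_numpy(), model,
                                        n_resample=cfg.n_resample, seed=cfg.seed)
    except ValueError as exc:
        raise RuntimeError(f"stage call: {exc}") from exc
    candidates = calling.call_sifs(filtered, cfg.ftr, cfg.fdr_threshold, table)
    sifs = calling.merge_equal_score(candidates, fmap)
    report["stages"]["call"] = {
        "input": len(filtered), "candidates": len(candidates),
        "sifs": len(sifs),
        "fdr_by_score": {int(s): float(f) for s, f in table.table["fdr"].items()},
    }
    return sifs, report
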