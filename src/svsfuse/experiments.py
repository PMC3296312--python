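"""End-to-end simulation protocol: generate sets, train SVS variants, fuse
every test with all methods, and summarize.

The protocol trains up to three SVS variants — SVS-2D (trained on the 2D
set), SVS-3D (3D set), SVS-2D&3D (both) — and applies them, alongside plain
STAPLE, Vote, and SBA, to an independently seeded testing set.  Per-test
records carry the Gaussian deformation parameters, the dissimilarity
factors, the selected method, and each method's v_D and DSC; tests are
grouped by the reference variant's selection ("Group STAPLE" / "Group SBA")
for the group-wise comparisons.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dissimilarity import DEFAULT_B, dissimilarity_factors
from .metrics import dsc, vd
from .shape_sim import calibrate_sigma, iter_protocol
from .svs import METHODS, ScoringModel, meta_fuse, run_all_fusers

logger = logging.getLogger(__name__)

VARIANT_NAMES = {"2d": "SVS-2D", "3d": "SVS-3D", "2d3d": "SVS-2D&3D"}


@dataclass
class ProtocolConfig:
    dims: tuple = ("2d",)            # dimensions to test on
    svs_variants: tuple = ("2d",)    # which training sets to build
    n_grid: int = 10                 # 10 -> 100 tests; 25 -> the full 625
    raters_per_test: int = 10
    train_seed: int = 1000
    test_seed: int = 2000
    B: int = DEFAULT_B
    span: float = 0.25

    def __post_init__(self):
        if self.raters_per_test < 2:
            raise ValueError("protocol needs at least 2 raters per test")
        if self.train_seed == self.test_seed:
            raise ValueError("training and testing seeds must differ")


@dataclass
class ProtocolReport:
    """Per-test records and per-method/group aggregates of one run."""

    records: pd.DataFrame
    models: dict = field(default_factory=dict)  # variant name -> ScoringModel
    config: ProtocolConfig | None = None

    def summary(self) -> dict:
        """Mean/median v_D and DSC per method, overall and per group."""
        df = self.records[~self.records["degenerate"]]
        methods = [c[3:] for c in df.columns if c.startswith("vD_")]
        out = {"n_tests": int(len(df)), "overall": {}, "groups": {}}
        for m in methods:
            out["overall"][m] = {
                "mean_vD": float(df[f"vD_{m}"].mean()),
                "median_vD": float(df[f"vD_{m}"].median()),
                "mean_DSC": float(df[f"DSC_{m}"].mean()),
            }
        if "group" in df.columns:
            for g, sub in df.groupby("group"):
                out["groups"][g] = {
                    m: {
                        "mean_vD": float(sub[f"vD_{m}"].mean()),
                        "mean_DSC": float(sub[f"DSC_{m}"].mean()),
                    }
                    for m in methods
                }
        return out

    def write(self, out_dir) -> None:
        os.makedirs(out_dir, exist_ok=True)
        self.records.to_csv(os.path.join(out_dir, "records.csv"), index=False)
        with open(os.path.join(out_dir, "summary.json"), "w") as fh:
            json.dump(self.summary(), fh, indent=2)
        for name, model in self.models.items():
            safe = name.replace("&", "").replace("-", "_").lower()
            model.save(os.path.join(out_dir, f"model_{safe}.json"))


def train_variants(config: ProtocolConfig, sigma_max: dict | None = None) -> dict:
    """Train the requested SVS variants on freshly generated training sets.

    Returns {variant display name: ScoringModel}.  The 2D&3D variant pools
    the scored points of both training sets by training on the concatenated
    test lists.
    """
    sigma_max = dict(sigma_max or {})
    sets: dict[str, list] = {}
    for dim in ("2d", "3d"):
        needed = dim in config.svs_variants or "2d3d" in config.svs_variants
        if not needed:
            continue
        if dim not in sigma_max:
            sigma_max[dim] = calibrate_sigma(dim, seed=config.train_seed)
        sets[dim] = list(
            iter_protocol(
                dim,
                n_grid=config.n_grid,
                raters_per_test=config.raters_per_test,
                seed=config.train_seed,
                sigma_max=sigma_max[dim],
            )
        )
    models = {}
    for variant in config.svs_variants:
        tests = sets["2d"] + sets["3d"] if variant == "2d3d" else sets[variant]
        models[VARIANT_NAMES[variant]] = ScoringModel.train(
            tests,
            span=config.span,
            B=config.B,
            provenance={"seed": config.train_seed, "set_id": variant},
        )
        logger.info("trained %s on %d tests", VARIANT_NAMES[variant], len(tests))
    return models


def evaluate_tests(
    tests,
    models: dict,
    B: int = DEFAULT_B,
    reference: str | None = None,
    set_id: str = "",
) -> pd.DataFrame:
    """Fuse every test with STAPLE/Vote/SBA and each SVS model, evaluate
    v_D and DSC against the truth, and label each test's group by the
    reference model's selection.  One row per test."""
    if reference is None:
        reference = (
            VARIANT_NAMES["2d3d"] if VARIANT_NAMES["2d3d"] in models
            else next(iter(models), None)
        )
    rows = []
    for i, test in enumerate(tests):
        pair = dissimilarity_factors(test.raters, B=B)
        row = {
            "set": set_id,
            "test": i,
            "mu_fs": test.mu_fs,
            "sd_fs": test.sd_fs,
            "d_c": pair.d_c,
            "d_r": pair.d_r,
            "degenerate": pair.unanimous,
        }
        if pair.unanimous:
            # all raters identical: every method returns the input
            r = vd(test.raters.grid, test.truth)
            for m in list(METHODS) + list(models):
                row[f"vD_{m}"] = r.v_D
                row[f"DSC_{m}"] = r.dsc
            row["group"] = "unanimous"
            rows.append(row)
            continue
        fusions = run_all_fusers(test.raters)
        for m in METHODS:
            r = vd(fusions[m], test.truth)
            row[f"vD_{m}"] = r.v_D
            row[f"DSC_{m}"] = r.dsc
        for name, model in models.items():
            scores = model.scores_at(pair.d_c, pair.d_r)
            ordered = sorted(scores.values(), reverse=True)
            if ordered[0] - ordered[1] <= 1e-9:
                label = meta_fuse(
                    [fusions[m] for m in METHODS],
                    [scores[m] for m in METHODS],
                )
                chosen = "meta"
                r = vd(label, test.truth)
            else:
                chosen = max(METHODS, key=lambda m: scores[m])
                r = vd(fusions[chosen], test.truth)
            row[f"vD_{name}"] = r.v_D
            row[f"DSC_{name}"] = r.dsc
            row[f"selected_{name}"] = chosen
            if name == reference:
                row["group"] = f"Group {chosen}"
        rows.append(row)
    return pd.DataFrame(rows)


def run_protocol(
    config: ProtocolConfig,
    models: dict | None = None,
    sigma_max: dict | None = None,
) -> ProtocolReport:
    """Run the full protocol: train (unless models are given), fuse every
    test of the testing set(s) with STAPLE/Vote/SBA and each SVS variant,
    evaluate v_D and DSC, and group by the reference variant's selection."""
    sigma_max = dict(sigma_max or {})
    if models is None:
        models = train_variants(config, sigma_max)

    frames = []
    for dim in config.dims:
        if dim not in sigma_max:
            sigma_max[dim] = calibrate_sigma(dim, seed=config.test_seed)
        tests = iter_protocol(
            dim,
            n_grid=config.n_grid,
            raters_per_test=config.raters_per_test,
            seed=config.test_seed,
            sigma_max=sigma_max[dim],
        )
        frames.append(evaluate_tests(tests, models, B=config.B, set_id=dim))

    return ProtocolReport(
        records=pd.concat(frames, ignore_index=True), models=models, config=config
    )


def centered_stats(report: ProtocolReport, reference: str = "VOTE") -> pd.DataFrame:
    """Per-test v_D and DSC centered on a reference method's values (the
    reference columns become identically zero)."""
    df = report.records
    out = df[["set", "test", "mu_fs", "sd_fs"]].copy()
    for prefix in ("vD", "DSC"):
        ref = df[f"{prefix}_{reference}"]
        for c in df.columns:
            if c.startswith(f"{prefix}_"):
                out[c] = df[c] - ref
    return out
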