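"""End-to-end orchestration: simulate or load -> groups -> density -> networks
-> IHPP -> SDE, with a reproducibility manifest.

All randomness flows from a single master seed, split per stage with a
``numpy`` SeedSequence, so one number reproduces a whole run.  Stage outputs
are delimited-text tables in the output directory; the manifest records the
package version, seeds, input digests and per-stage status.
"""

from __future__ import annotations

import hashlib
import json
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, io
from .errors import ColonyStateError
from .geometry import NestGeometry, build_nest, four_chamber_nest, one_chamber_nest

ALL_STAGES = ("groups", "density", "network", "ihpp", "sde")


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    mode: str  # "synthetic" | "files"
    out_dir: Path
    nest: NestGeometry
    seed: int = 0
    stages: tuple = ALL_STAGES
    scenario: dict = field(default_factory=dict)  # synthetic mode
    tracks_path: Path | None = None  # files mode
    events_path: Path | None = None
    perturb_reps: int = 0
    sde_grid_mm: float = 5.0

    @classmethod
    def from_mapping(cls, cfg: dict) -> "RunConfig":
        missing = [k for k in ("mode", "out_dir") if k not in cfg]
        if missing:
            raise ColonyStateError(f"config missing required fields: {missing}")
        mode = cfg["mode"]
        if mode not in ("synthetic", "files"):
            raise ColonyStateError("mode must be 'synthetic' or 'files'")
        nest_cfg = cfg.get("nest", "four_chamber")
        if isinstance(nest_cfg, str):
            nest = {
                "one_chamber": one_chamber_nest,
                "four_chamber": four_chamber_nest,
            }[nest_cfg]()
        else:
            nest = build_nest(nest_cfg)
        tracks_path = cfg.get("tracks")
        events_path = cfg.get("events")
        if mode == "files" and tracks_path is None:
            raise ColonyStateError("files mode requires a 'tracks' path")
        if mode == "files" and tracks_path and not Path(tracks_path).exists():
            raise ColonyStateError(f"tracks file not found: {tracks_path}")
        stages = tuple(cfg.get("stages", ALL_STAGES))
        unknown = set(stages) - set(ALL_STAGES)
        if unknown:
            raise ColonyStateError(f"unknown stages: {sorted(unknown)}")
        return cls(
            mode=mode,
            out_dir=Path(cfg["out_dir"]),
            nest=nest,
            seed=int(cfg.get("seed", 0)),
            stages=stages,
            scenario=dict(cfg.get("scenario", {})),
            tracks_path=Path(tracks_path) if tracks_path else None,
            events_path=Path(events_path) if events_path else None,
            perturb_reps=int(cfg.get("perturb_reps", 0)),
            sde_grid_mm=float(cfg.get("sde_grid_mm", 5.0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest.

    Identical config + seed give byte-identical stage outputs.  A stage
    failure is recorded in the manifest and in ``<stage>.status``; completed
    outputs are retained.
    """
    from . import density as dens
    from . import ihpp as ihpp_mod
    from . import interaction_network as inet
    from . import sde_movement as sde
    from . import spatial_groups as sg
    from . import synthetic_data as synth

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg.seed).spawn(len(ALL_STAGES) + 1)
    stage_seed = {
        name: int(s.generate_state(1)[0] % (2**31 - 1))
        for name, s in zip(("input",) + ALL_STAGES, seeds)
    }
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "stage_seeds": stage_seed,
        "mode": cfg.mode,
        "stages": {},
        "inputs": {},
    }

    # -- input stage --------------------------------------------------------
    if cfg.mode == "synthetic":
        scen_kwargs = dict(cfg.scenario)
        scen_kwargs.setdefault("seed", stage_seed["input"])
        scenario = synth.ColonyScenario(nest=cfg.nest, **scen_kwargs)
        colony = synth.simulate_colony(scenario)
        tracks, events = colony.tracks, colony.events
        io.write_tracks(tracks, out / "tracks.csv")
        io.write_events(events, out / "events.csv")
        (out / "ground_truth.json").write_text(
            json.dumps(
                {
                    "groups": colony.true_groups,
                    "beta": scenario.beta,
                    "motility": scenario.motility,
                    "well_strength": scenario.well_strength,
                    "ihpp_coefs": vars(scenario.ihpp_coefs)
                    if not hasattr(scenario.ihpp_coefs, "__dataclass_fields__")
                    else {
                        k: getattr(scenario.ihpp_coefs, k)
                        for k in scenario.ihpp_coefs.__dataclass_fields__
                    },
                },
                indent=1,
                sort_keys=True,
            )
        )
    else:
        from .preprocess import preprocess_tracks

        frame = io.read_tracks(cfg.tracks_path)
        manifest["inputs"]["tracks"] = _digest(cfg.tracks_path)
        duration = int(frame["t_s"].max())
        tracks = preprocess_tracks(frame, cfg.nest, duration=duration)
        events = []
        if cfg.events_path is not None:
            events = io.read_events(cfg.events_path)
            manifest["inputs"]["events"] = _digest(cfg.events_path)

    partition = None
    for stage in cfg.stages:
        t0 = time.perf_counter()
        status = "ok"
        try:
            if stage == "groups":
                partition = sg.spatial_partition(
                    tracks, cfg.nest, seed=stage_seed["groups"]
                )
                sigs = {
                    s.ant_id: s.mean
                    for s in (sg.spatial_signature(tr, cfg.nest) for tr in tracks)
                }
                rows = [
                    f"{a},{g},{sigs.get(a, float('nan')):.3f}"
                    for a, g in sorted(partition.labels.items())
                ]
                (out / "partition.csv").write_text(
                    "ant_id,group,mean_entrance_distance_mm\n" + "\n".join(rows) + "\n"
                )
                if cfg.perturb_reps:
                    net = sg.build_similarity_network(
                        [
                            s
                            for s in (
                                sg.spatial_signature(tr, cfg.nest) for tr in tracks
                            )
                            if not s.empty
                        ]
                    )
                    res = sg.perturb_and_score(
                        net,
                        partition,
                        sg.PerturbationConfig(
                            n_reps=cfg.perturb_reps, seed=stage_seed["groups"]
                        ),
                    )
                    (out / "perturbation.json").write_text(
                        json.dumps(
                            {
                                "changed_fraction": res.changed_fraction,
                                "max_changed_fraction": res.max_changed_fraction,
                            },
                            indent=1,
                        )
                    )
            elif stage == "density":
                series = dens.local_density(tracks, cfg.nest)
                mean = series.mean_over_ants
                lines = ["t_s,mean_density"] + [
                    f"{t},{m:.6f}" for t, m in enumerate(mean)
                ]
                (out / "mean_density.csv").write_text("\n".join(lines) + "\n")
                sub = dens.decorrelate(series, seed=stage_seed["density"])
                lines = ["t_s,mean_density"] + [
                    f"{t * sub.interval},{v:.6f}" for t, v in enumerate(sub.values)
                ]
                (out / "density_subsampled.csv").write_text("\n".join(lines) + "\n")
            elif stage == "network":
                net = inet.build_network(events, roster=[tr.ant_id for tr in tracks])
                counts = inet.interaction_count_series(
                    events, duration=tracks[0].n_seconds - 1
                )
                report = {"n_events": int(counts.counts.sum())}
                if partition is not None and net.number_of_edges() > 0:
                    res = inet.assortativity(net, partition)
                    report.update({"r": res.r, "se": res.se, "z": res.z})
                (out / "network_report.json").write_text(json.dumps(report, indent=1))
            elif stage == "ihpp":
                table = ihpp_mod.pair_second_table(tracks, cfg.nest, events=events)
                fit = ihpp_mod.fit_ihpp(table)
                fit.table.to_csv(out / "ihpp_table.csv")
                ihpp_mod.rate_effects(fit).to_csv(
                    out / "ihpp_rate_effects.csv", index=False
                )
            elif stage == "sde":
                records = sde.build_regression(tracks)
                fit = sde.fit_sde(records, cfg.nest, grid_mm=cfg.sde_grid_mm)
                df, chamber_means = sde.surface_report(fit)
                df.to_csv(out / "sde_surfaces.csv", index=False)
                (out / "sde_summary.json").write_text(
                    json.dumps(
                        {
                            "beta": fit.beta,
                            "chamber_mean_motility": chamber_means,
                        },
                        indent=1,
                    )
                )
        except Exception as exc:  # retain partial outputs, record failure
            status = f"failed: {exc}"
            (out / f"{stage}.status").write_text(
                status + "\n" + traceback.format_exc()
            )
        manifest["stages"][stage] = {
            "status": status,
            "wall_time_s": round(time.perf_counter() - t0, 3),
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
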