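"""End-to-end five-stage run driven by a config file.

One run executes, for the base structure and each named truncation:

1. load + coarse-grain + static buried-core survey,
2. pulling-axis alignment,
3. elastic-network modes (full spectrum, so stiffness is available),
4. per-residue fluctuations/stiffness, per-mode collectivity and axis
   components, separating-mode selection,
5. target-RMSD ensembles and an RMSD ramp along the selected modes,
   ensemble burial statistics, and a domain integrity ranking (the domain
   with the lowest mean buried volume is flagged as coming apart first).

Every number that reaches the report also exists as a CSV under the output
directory; plots are illustrations, never the primary record.  A manifest
echoes the config, so a run can be replayed exactly.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pullnma.version import __version__ as _version
from pullnma.burial import BurialParameters, burial_report, ensemble_burial
from pullnma.deformation import DeformationSpec, derive_subseed, rmsd_ramp, sample_ensemble
from pullnma.enm import ENMParameters, compute_enm_modes
from pullnma.errors import ConfigError
from pullnma.fixtures import DumbbellSpec, make_dimer, make_dumbbell, make_helix
from pullnma.geometry import PullingGeometry, align_pulling_axis
from pullnma.mode_analysis import (
    DomainMap,
    ModeSelectionCriteria,
    axis_components,
    residue_stiffness,
    select_separating_modes,
    square_fluctuations,
)
from pullnma.structure_io import (
    CoarseModel,
    ResidueRangeSelection,
    apply_selection,
    extract_ca,
    parse_ranges,
    read_pdb,
    write_coarse_pdb,
)

logger = logging.getLogger(__name__)


def _check_keys(d: dict, allowed: set[str], context: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {context} "
                          f"(allowed: {sorted(allowed)})")


@dataclass
class RunConfig:
    """Validated run configuration (see ``RunConfig.from_dict`` for the schema)."""

    structure: dict
    pulling: dict | None
    domains: dict[str, str] | None
    truncations: list[tuple[str, ResidueRangeSelection]]
    enm: ENMParameters
    selection: ModeSelectionCriteria
    deformation: dict
    burial: BurialParameters
    output_dir: Path
    seed: int
    raw: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        _check_keys(
            d,
            {"structure", "pulling", "domains", "truncations", "enm", "selection",
             "deformation", "burial", "output_dir", "seed"},
            "run config",
        )
        structure = d.get("structure")
        if not isinstance(structure, dict):
            raise ConfigError("'structure' section is required")
        _check_keys(structure, {"path", "chains", "model_index", "fixture"}, "structure")
        if ("path" in structure) == ("fixture" in structure):
            raise ConfigError("structure needs exactly one of 'path' or 'fixture'")
        if "fixture" in structure:
            fx = structure["fixture"]
            _check_keys(
                fx,
                {"kind", "n_per_lobe", "lobe_packing_radius", "linker_length",
                 "separation", "seed", "n_residues", "d0"},
                "structure.fixture",
            )
            if fx.get("kind") not in ("dumbbell", "helix", "dimer"):
                raise ConfigError("fixture.kind must be dumbbell, helix or dimer")

        pulling = d.get("pulling")
        if pulling is not None:
            _check_keys(pulling, {"attach_a", "attach_b", "axis"}, "pulling")

        domains = d.get("domains")
        if domains is not None and not isinstance(domains, dict):
            raise ConfigError("'domains' must map names to residue-range strings")

        truncations = []
        for entry in d.get("truncations", []) or []:
            _check_keys(entry, {"name", "remove", "keep"}, "truncation entry")
            if "name" not in entry or ("remove" in entry) == ("keep" in entry):
                raise ConfigError("each truncation needs 'name' and one of 'remove'/'keep'")
            if "remove" in entry:
                sel = parse_ranges(entry["remove"], mode="remove")
            else:
                sel = parse_ranges(entry["keep"], mode="keep")
            truncations.append((str(entry["name"]), sel))

        enm_d = d.get("enm", {}) or {}
        _check_keys(enm_d, {"cutoff", "gamma", "n_modes"}, "enm")
        enm = ENMParameters(
            cutoff_rc=float(enm_d.get("cutoff", 15.0)),
            gamma=float(enm_d.get("gamma", 1.0)),
            n_modes=enm_d.get("n_modes", "all"),
        )

        sel_d = d.get("selection", {}) or {}
        _check_keys(
            sel_d,
            {"first_k", "top_collectivity", "of_first", "opposite_sign", "min_separation"},
            "selection",
        )
        selection = ModeSelectionCriteria(
            first_k=int(sel_d.get("first_k", 10)),
            top_collectivity=int(sel_d.get("top_collectivity", 10)),
            of_first=int(sel_d.get("of_first", 50)),
            opposite_sign_required=bool(sel_d.get("opposite_sign", True)),
            min_separation=float(sel_d.get("min_separation", 0.25)),
        )

        def_d = d.get("deformation", {}) or {}
        _check_keys(
            def_d,
            {"target_rmsd", "ramp", "n_conformations", "n_per_step", "weighting", "modes"},
            "deformation",
        )
        deformation = {
            "target_rmsd": float(def_d.get("target_rmsd", 12.0)),
            "ramp": [float(t) for t in def_d.get("ramp", [2, 4, 6, 8, 10, 12])],
            "n_conformations": int(def_d.get("n_conformations", 500)),
            "n_per_step": int(def_d.get("n_per_step", 50)),
            "weighting": str(def_d.get("weighting", "inverse_lambda")),
            "modes": def_d.get("modes"),  # optional manual override of selection
        }

        bur_d = d.get("burial", {}) or {}
        _check_keys(
            bur_d, {"probe_radius", "n_sphere_points", "exposure_threshold"}, "burial"
        )
        burial = BurialParameters(
            probe_radius=float(bur_d.get("probe_radius", 1.4)),
            n_sphere_points=int(bur_d.get("n_sphere_points", 960)),
            exposure_threshold=float(bur_d.get("exposure_threshold", 0.05)),
        )

        return cls(
            structure=structure,
            pulling=pulling,
            domains=domains,
            truncations=truncations,
            enm=enm,
            selection=selection,
            deformation=deformation,
            burial=burial,
            output_dir=Path(d.get("output_dir", "pullnma_out")),
            seed=int(d.get("seed", 0)),
            raw=d,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} did not parse to a mapping")
        return cls.from_dict(data)


@dataclass
class RunReport:
    """Everything a run produced, with provenance."""

    output_dir: Path
    manifest: dict
    rankings: dict[str, pd.DataFrame]
    warnings: list[str]
    timings: dict[str, float]

    def integrity_ranking(self, variant: str = "full") -> pd.DataFrame:
        """Domains sorted by ascending mean buried volume at the largest target
        (lowest = weakest structural integrity)."""
        return self.rankings[variant]


def _load_structure(cfg: RunConfig):
    """Returns (model, fixture_domains, fixture_pull)."""
    st = cfg.structure
    if "path" in st:
        structure = read_pdb(st["path"])
        model = extract_ca(
            structure,
            chains=st.get("chains"),
            model_index=int(st.get("model_index", 1)),
        )
        return model, None, None
    fx = dict(st["fixture"])
    kind = fx.pop("kind")
    if kind == "dumbbell":
        spec_kwargs = {k: fx[k] for k in
                       ("n_per_lobe", "lobe_packing_radius", "linker_length", "separation", "seed")
                       if k in fx}
        if "lobe_packing_radius" in spec_kwargs and isinstance(spec_kwargs["lobe_packing_radius"], list):
            spec_kwargs["lobe_packing_radius"] = tuple(spec_kwargs["lobe_packing_radius"])
        model, dm, pull = make_dumbbell(DumbbellSpec(**spec_kwargs))
        return model, dm, pull
    if kind == "helix":
        return make_helix(int(fx.get("n_residues", 20))), None, None
    return make_dimer(float(fx.get("d0", 3.8))), None, None


def _axis_vector(name) -> np.ndarray:
    named = {"x": (1, 0, 0), "y": (0, 1, 0), "z": (0, 0, 1)}
    if isinstance(name, str):
        if name not in named:
            raise ConfigError(f"axis must be one of {sorted(named)}, got {name!r}")
        return np.array(named[name], dtype=float)
    return np.asarray(name, dtype=float)


def _plot_series(path, series: dict[str, tuple[np.ndarray, np.ndarray]],
                 xlabel: str, ylabel: str, title: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.2))
    for label, (x, y) in series.items():
        ax.plot(x, y, label=label, lw=1.0)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_title(title, fontsize=9)
    if len(series) > 1:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the five-stage workflow for the base structure and each truncation."""
    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": _version,
        "seed": config.seed,
        "config": config.raw,
        "variants": {},
    }
    collected_warnings: list[str] = []
    timings: dict[str, float] = {}
    rankings: dict[str, pd.DataFrame] = {}

    base_model, fixture_dm, fixture_pull = _load_structure(config)

    variants: list[tuple[str, ResidueRangeSelection | None]] = [("full", None)]
    variants += [(name, sel) for name, sel in config.truncations]

    for v_index, (v_name, v_sel) in enumerate(variants):
        t_variant = time.time()
        out = out_root / v_name
        out.mkdir(exist_ok=True)
        files: dict[str, str] = {}
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")

            # -- stage 1: load / truncate / static burial survey -------------
            t0 = time.time()
            model = base_model if v_sel is None else apply_selection(base_model, v_sel)
            if config.domains is not None:
                dm = DomainMap.from_ranges(model, config.domains)
            elif fixture_dm is not None and v_sel is None:
                dm = fixture_dm
            else:
                dm = None
            static = burial_report(model, config.burial, domains=dm)
            static_df = static.to_frame(model)
            static_df.to_csv(out / "static_burial.csv", index=False)
            files["static_burial"] = "static_burial.csv"
            timings[f"{v_name}/survey"] = time.time() - t0

            # -- stage 2: pulling-axis alignment ------------------------------
            t0 = time.time()
            if config.pulling is not None:
                pull = PullingGeometry(
                    attach_a=config.pulling["attach_a"],
                    attach_b=config.pulling["attach_b"],
                    target_axis=_axis_vector(config.pulling.get("axis", "z")),
                )
            elif fixture_pull is not None:
                pull = fixture_pull
            else:
                raise ConfigError("no pulling geometry given and none provided by the fixture")
            aligned, transform = align_pulling_axis(model, pull)
            axis = pull.target_axis
            (out / "alignment.json").write_text(json.dumps({
                "attach_a": list(map(str, pull.attach_a)) if not isinstance(pull.attach_a, str) else pull.attach_a,
                "attach_b": list(map(str, pull.attach_b)) if not isinstance(pull.attach_b, str) else pull.attach_b,
                "target_axis": axis.tolist(),
                "transform": transform.as_flat(),
            }, indent=2))
            files["alignment"] = "alignment.json"
            timings[f"{v_name}/align"] = time.time() - t0

            # -- stage 3: normal modes ----------------------------------------
            t0 = time.time()
            modes = compute_enm_modes(aligned, config.enm)
            modes.to_nmd(out / "modes.nmd",
                         labels=[r.residue_seq for r in aligned.residue_ids])
            files["modes"] = "modes.nmd"
            timings[f"{v_name}/modes"] = time.time() - t0

            # -- stage 4: observables + mode selection ------------------------
            t0 = time.time()
            fluct = square_fluctuations(modes, m_modes=min(100, modes.n_modes))
            per_res = pd.DataFrame({
                "chain": [r.chain_id for r in aligned.residue_ids],
                "residue_seq": [r.residue_seq for r in aligned.residue_ids],
                "residue_name": aligned.residue_names,
                "square_fluctuation": fluct,
            })
            if modes.is_complete:
                per_res["stiffness"] = residue_stiffness(modes)
            per_res.to_csv(out / "per_residue.csv", index=False)
            files["per_residue"] = "per_residue.csv"
            _plot_series(out / "fluctuations.png",
                         {"fluctuation": (per_res["residue_seq"].to_numpy(), fluct)},
                         "residue", "square fluctuation (rel.)", f"{v_name}: fluctuations")

            selected: list[int] = []
            if dm is not None and len(dm) == 2:
                selected, report = select_separating_modes(modes, dm, axis, config.selection)
                report.to_csv(out / "mode_report.csv", index=False)
                files["mode_report"] = "mode_report.csv"
                zcomp = {}
                for k in selected[:8]:
                    zcomp[f"mode_{k}"] = axis_components(modes, k, axis)
                if zcomp:
                    zdf = pd.DataFrame({"residue_seq": per_res["residue_seq"], **zcomp})
                    zdf.to_csv(out / "axis_components.csv", index=False)
                    files["axis_components"] = "axis_components.csv"
                    _plot_series(out / "axis_components.png",
                                 {k: (zdf["residue_seq"].to_numpy(), v.to_numpy())
                                  for k, v in zdf.drop(columns="residue_seq").items()},
                                 "residue", "axis component", f"{v_name}: selected-mode axis components")
            if config.deformation["modes"]:
                selected = [int(k) for k in config.deformation["modes"]]
            timings[f"{v_name}/analysis"] = time.time() - t0

            # -- stage 5: ensembles + burial + ranking ------------------------
            t0 = time.time()
            if selected and dm is not None:
                spec = DeformationSpec(
                    mode_indices=tuple(selected),
                    target_rmsd=config.deformation["target_rmsd"],
                    n_conformations=config.deformation["n_conformations"],
                    seed=derive_subseed(config.seed, 1000 + v_index),
                    weighting=config.deformation["weighting"],
                )
                ensemble = sample_ensemble(modes, spec, reference=aligned)
                write_coarse_pdb(ensemble, out / "ensemble.pdb")
                ensemble.coefficient_table().to_csv(out / "ensemble_coefficients.csv", index=False)
                files["ensemble"] = "ensemble.pdb"
                stats = ensemble_burial(ensemble, dm, config.burial)
                main_summary = stats.summary()
                main_summary["stage"] = "target"
                rows = [main_summary]

                ramp = rmsd_ramp(
                    modes, selected, config.deformation["ramp"],
                    n_per_step=config.deformation["n_per_step"],
                    seed=config.seed,
                    weighting=config.deformation["weighting"],
                    reference=aligned,
                )
                for ens in ramp:
                    step_summary = ensemble_burial(ens, dm, config.burial).summary()
                    step_summary["stage"] = "ramp"
                    rows.append(step_summary)
                burial_df = pd.concat(rows, ignore_index=True)
                burial_df.to_csv(out / "ensemble_burial.csv", index=False)
                files["ensemble_burial"] = "ensemble_burial.csv"

                ramp_rows = burial_df[burial_df["stage"] == "ramp"]
                ramp_series = {
                    name: (ramp_rows[ramp_rows["domain"] == name]
                           .sort_values("target_rmsd")["target_rmsd"].to_numpy(),
                           ramp_rows[ramp_rows["domain"] == name]
                           .sort_values("target_rmsd")["mean_buried_volume"].to_numpy())
                    for name in dm
                }
                _plot_series(out / "buried_volume_ramp.png", ramp_series,
                             "target RMSD (Å)", "mean buried volume (Å³)",
                             f"{v_name}: buried volume vs distortion")

                main = stats.summary().sort_values("mean_buried_volume").reset_index(drop=True)
                main["integrity_rank"] = np.arange(1, len(main) + 1)  # 1 = weakest
                main.to_csv(out / "integrity_ranking.csv", index=False)
                files["integrity_ranking"] = "integrity_ranking.csv"
                rankings[v_name] = main
            else:
                logger.info("variant %s: no separating modes selected; stage 5 ensembles skipped", v_name)
            timings[f"{v_name}/deform_burial"] = time.time() - t0

        collected_warnings.extend(f"{v_name}: {w.message}" for w in caught)
        manifest["variants"][v_name] = {
            "files": files,
            "n_sites": model.n_sites,
            "n_zero_modes": modes.n_zero_modes,
            "selected_modes": selected,
            "seconds": round(time.time() - t_variant, 3),
        }

    manifest["warnings"] = collected_warnings
    manifest["timings"] = {k: round(v, 3) for k, v in timings.items()}
    (out_root / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return RunReport(
        output_dir=out_root,
        manifest=manifest,
        rankings=rankings,
        warnings=collected_warnings,
        timings=timings,
    )
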