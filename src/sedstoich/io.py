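"""File formats, manifests, configuration and the pipeline driver.

Everything on disk is plain text: radial scans are two-column CSV
(radius_cm, absorbance), scan sets and equilibrium datasets are a directory
of CSVs plus a YAML manifest carrying rotor speed, times, reference radius,
cell geometry, seed and per-file MD5 checksums; distributions are CSV with
``#`` metadata headers; fit reports are JSON embedding the fully resolved
configuration and seeds so every result regenerates from its report.

:func:`run_pipeline` ties the stages together
(simulate -> fit-se / fit-cs -> stoich / titration) from a single config
mapping; stage names are validated before anything executes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from .exceptions import ConfigError, InvalidInputError, ParseError
from .lamm import CellGeometry, SVScanSet
from .physchem import BufferState, Component, molar_mass_from_sequence
from .se_analysis import (
    SEProfile,
    fit_one_species_global,
    fit_two_species_global,
)
from .stoichiometry import CopyRule, enumerate_matches
from .sv_analysis import CsDistribution, default_s_grid, fit_cs, weight_average_s
from .titration import TitrationSeries, detect_onset, normalize_series

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
KNOWN_STAGES = ("simulate", "fit-se", "fit-cs", "stoich", "titration")


def _md5(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Radial scan CSV
# ---------------------------------------------------------------------------


class RadialScan:
    """A single radial absorbance scan with optional metadata."""

    def __init__(self, radii, values, meta=None):
        self.radii = np.asarray(radii, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self.meta = dict(meta or {})

    def __len__(self):
        return self.radii.size


def read_scan_csv(path) -> RadialScan:
    """Parse a two-column (radius_cm, absorbance) CSV with validation.

    Duplicate radii are collapsed by averaging (with a logged warning);
    radii that still fail to increase strictly, or any non-numeric row,
    raise :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    rows: list[tuple[float, float]] = []
    data_started = False
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = [p.strip() for p in stripped.split(",")]
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {line!r}")
        if not data_started:
            # a single header row is allowed
            try:
                float(parts[0])
            except ValueError:
                data_started = True
                continue
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: non-numeric data {line!r}"
            ) from None
        data_started = True
    if not rows:
        raise ParseError(f"{path}: no data rows")
    radii = np.array([r for r, _ in rows])
    values = np.array([v for _, v in rows])
    if np.any(np.diff(radii) < 0):
        bad = int(np.argmax(np.diff(radii) < 0)) + 2
        raise ParseError(
            f"{path}: radii decrease around data row {bad}; scans must be "
            "radially ordered"
        )
    if np.any(np.diff(radii) == 0):
        uniq, inverse = np.unique(radii, return_inverse=True)
        collapsed = np.zeros_like(uniq)
        counts = np.zeros_like(uniq)
        np.add.at(collapsed, inverse, values)
        np.add.at(counts, inverse, 1.0)
        logger.warning(
            "%s: %d duplicated radii collapsed by mean",
            path, radii.size - uniq.size,
        )
        radii, values = uniq, collapsed / counts
    return RadialScan(radii, values)


def write_scan_csv(path, radii, values) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("radius_cm,absorbance\n")
        for r, v in zip(np.asarray(radii), np.asarray(values)):
            fh.write(f"{r:.6f},{v:.8g}\n")


# ---------------------------------------------------------------------------
# SV scan sets
# ---------------------------------------------------------------------------


def write_sv_scanset(scans: SVScanSet, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for k, t in enumerate(scans.times):
        name = f"scan_{k:03d}.csv"
        write_scan_csv(outdir / name, scans.radius_grid, scans.signals[k])
        files.append(
            {"file": name, "time_s": float(t), "md5": _md5(outdir / name)}
        )
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "kind": "sv",
        "rpm": float(scans.rpm),
        "wavelength_nm": float(scans.wavelength_nm),
        "meniscus": float(scans.geometry.meniscus),
        "bottom": float(scans.geometry.bottom),
        "seed": scans.seed,
        "noise_sigma": float(scans.noise_sigma),
        "files": files,
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    return outdir


def _check_manifest(manifest: dict, outdir: Path) -> None:
    version = manifest.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ParseError(
            f"{outdir}: unsupported manifest schema_version {version!r}"
        )
    for entry in manifest.get("files", []):
        fpath = outdir / entry["file"]
        if not fpath.exists():
            raise ParseError(f"{outdir}: missing file {entry['file']!r}")
        if "md5" in entry and _md5(fpath) != entry["md5"]:
            raise ParseError(f"{outdir}: checksum mismatch for {entry['file']!r}")


def read_sv_scanset(outdir) -> SVScanSet:
    outdir = Path(outdir)
    manifest = yaml.safe_load((outdir / "manifest.yaml").read_text())
    _check_manifest(manifest, outdir)
    times, signals = [], []
    radius_grid = None
    for entry in manifest["files"]:
        scan = read_scan_csv(outdir / entry["file"])
        times.append(entry["time_s"])
        signals.append(scan.values)
        radius_grid = scan.radii
    return SVScanSet(
        geometry=CellGeometry(manifest["meniscus"], manifest["bottom"]),
        rpm=manifest["rpm"],
        times=np.asarray(times),
        radius_grid=radius_grid,
        signals=np.asarray(signals),
        noise_sigma=manifest.get("noise_sigma", 0.0),
        seed=manifest.get("seed"),
        wavelength_nm=manifest.get("wavelength_nm", 546.0),
    )


# ---------------------------------------------------------------------------
# SE profile sets
# ---------------------------------------------------------------------------


def write_se_profiles(profiles: list[SEProfile], outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for k, prof in enumerate(profiles):
        name = f"equil_{int(prof.rpm):05d}rpm_{k:02d}.csv"
        write_scan_csv(outdir / name, prof.radius_grid, prof.signal)
        files.append(
            {
                "file": name,
                "rpm": float(prof.rpm),
                "r0": float(prof.r0),
                "meniscus": float(prof.geometry.meniscus),
                "bottom": float(prof.geometry.bottom),
                "md5": _md5(outdir / name),
            }
        )
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "kind": "se",
        "files": files,
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    return outdir


def read_se_profiles(outdir) -> list[SEProfile]:
    outdir = Path(outdir)
    manifest = yaml.safe_load((outdir / "manifest.yaml").read_text())
    _check_manifest(manifest, outdir)
    profiles = []
    for entry in manifest["files"]:
        scan = read_scan_csv(outdir / entry["file"])
        profiles.append(
            SEProfile(
                rpm=entry["rpm"],
                radius_grid=scan.radii,
                signal=scan.values,
                r0=entry["r0"],
                geometry=CellGeometry(entry["meniscus"], entry["bottom"]),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# c(s) distribution CSV
# ---------------------------------------------------------------------------


def write_cs_distribution(dist: CsDistribution, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# frictional_ratio: {dist.frictional_ratio:.8g}\n")
        fh.write(f"# regularization_alpha: {dist.regularization_alpha:.8g}\n")
        fh.write(f"# fit_rmsd: {dist.fit_rmsd:.8g}\n")
        fh.write("s_svedberg,c_of_s\n")
        for s, c in zip(dist.s_grid, dist.amplitudes):
            fh.write(f"{s:.8g},{c:.8g}\n")


def read_cs_distribution(path) -> CsDistribution:
    path = Path(path)
    meta = {}
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = float(val)
    scan = read_scan_csv(path)
    return CsDistribution(
        s_grid=scan.radii,
        amplitudes=scan.values,
        frictional_ratio=meta.get("frictional_ratio", 1.2),
        regularization_alpha=meta.get("regularization_alpha", 0.0),
        fit_rmsd=meta.get("fit_rmsd", 0.0),
    )


# ---------------------------------------------------------------------------
# Titration CSV
# ---------------------------------------------------------------------------


def write_titration_csv(series: TitrationSeries, path) -> None:
    """Rows: injection_index, molar_ratio, intensity_counts; row 0 is I_0."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("injection_index,molar_ratio,intensity_counts\n")
        fh.write(f"0,0,{series.initial_intensity:.8g}\n")
        for i, (ratio, intensity) in enumerate(
            zip(series.molar_ratios, series.intensities), start=1
        ):
            fh.write(f"{i},{ratio:.8g},{intensity:.8g}\n")


def read_titration_csv(path, reference_path=None) -> TitrationSeries:
    path = Path(path)
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split(",")
        if parts[0] == "injection_index":
            continue
        try:
            rows.append((int(parts[0]), float(parts[1]), float(parts[2])))
        except (ValueError, IndexError):
            raise ParseError(f"{path}:{lineno}: bad titration row {line!r}") from None
    if not rows:
        raise ParseError(f"{path}: no data rows")
    rows.sort()
    i0_rows = [r for r in rows if r[0] == 0]
    if not i0_rows:
        raise ParseError(f"{path}: missing injection_index 0 row carrying I_0")
    i0 = i0_rows[0][2]
    data = [(ratio, inten) for idx, ratio, inten in rows if idx > 0]
    reference = None
    if reference_path is not None:
        ref = read_titration_csv(reference_path)
        if ref.intensities.size != len(data):
            raise InvalidInputError("reference series length mismatch")
        reference = ref.intensities
    return TitrationSeries(
        molar_ratios=np.array([r for r, _ in data]),
        intensities=np.array([v for _, v in data]),
        initial_intensity=i0,
        reference_intensities=reference,
    )


# ---------------------------------------------------------------------------
# Registry and rules files
# ---------------------------------------------------------------------------


def load_registry_yaml(path) -> dict[str, Component]:
    """Load a component registry; derives masses from sequences if needed."""
    raw = yaml.safe_load(Path(path).read_text())
    registry = {}
    for name, rec in raw.items():
        mass = rec.get("molar_mass")
        if mass is None:
            if "sequence" not in rec:
                raise ConfigError(
                    f"component {name!r}: need molar_mass or sequence"
                )
            mass = molar_mass_from_sequence(
                rec["sequence"], rec.get("kind", "peptide"),
                rec.get("adducts", ()),
            )
            logger.info("derived molar mass %.1f g/mol for %s", mass, name)
        registry[name] = Component(
            name=name,
            molar_mass=float(mass),
            vbar=float(rec["vbar"]),
            extinction={
                float(k): float(v)
                for k, v in (rec.get("extinction") or {}).items()
            },
            kind=rec.get("kind", "protein"),
            sequence=rec.get("sequence"),
        )
    return registry


def write_registry_yaml(registry: dict[str, Component], path) -> None:
    raw = {}
    for name, comp in registry.items():
        rec = {
            "molar_mass": float(comp.molar_mass),
            "vbar": float(comp.vbar),
            "kind": comp.kind,
        }
        if comp.extinction:
            rec["extinction"] = {
                float(k): float(v) for k, v in comp.extinction.items()
            }
        if comp.sequence:
            rec["sequence"] = comp.sequence
        raw[name] = rec
    Path(path).write_text(yaml.safe_dump(raw))


def load_rules_yaml(path) -> list[CopyRule]:
    raw = yaml.safe_load(Path(path).read_text()) or []
    rules = []
    for rec in raw:
        if "allowed" in rec:
            rules.append(
                CopyRule(
                    component=rec["component"],
                    allowed=tuple(int(x) for x in rec["allowed"]),
                )
            )
        else:
            rules.append(
                CopyRule(
                    component=rec["component"],
                    op=rec["op"],
                    other=rec["other"],
                )
            )
    return rules


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------


def _se_fit_to_dict(result) -> dict:
    return {
        "masses_g_per_mol": [
            {"value": m, "standard_error": se} for m, se in result.masses
        ],
        "amplitudes": result.amplitudes.tolist(),
        "baselines": result.baselines.tolist(),
        "reduced_chisq": result.reduced_chisq,
        "fractions": result.fractions.tolist(),
        "mass_conservation": result.mass_conservation,
    }


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Execute the configured stages and return the report bundle.

    The config is a mapping with optional ``seed``, ``buffer`` (density /
    viscosity / temperature), ``registry`` (path to a YAML registry), and
    a ``stages`` list; each stage entry carries ``stage`` (one of
    simulate | fit-se | fit-cs | stoich | titration) plus stage-specific
    parameters.  Unknown stage names or missing referenced files fail
    validation before any stage runs.  The report embeds the resolved
    configuration and all seeds.
    """
    from . import synthetic_data as synth

    stages = config.get("stages", [])
    for entry in stages:
        name = entry.get("stage")
        if name not in KNOWN_STAGES:
            raise ConfigError(
                f"unknown stage {name!r}; known: {KNOWN_STAGES}"
            )
    registry_path = config.get("registry")
    if registry_path is not None and not Path(registry_path).exists():
        raise ConfigError(f"registry file not found: {registry_path}")
    for entry in stages:
        for key in ("input", "reference"):
            if key in entry and not Path(entry[key]).exists():
                raise ConfigError(
                    f"stage {entry['stage']!r}: missing {key} file "
                    f"{entry[key]!r}"
                )

    seed = int(config.get("seed", 0))
    buf_cfg = config.get("buffer", {})
    buffer = BufferState(
        density=buf_cfg.get("density", 1.05),
        viscosity=buf_cfg.get("viscosity", 0.010),
        temperature=buf_cfg.get("temperature", 298.15),
    )
    registry = (
        load_registry_yaml(registry_path)
        if registry_path
        else synth.reference_registry()
    )
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    workspace: dict = {}
    report: dict = {"config": config, "seed": seed, "stages": {}}
    for entry in stages:
        name = entry["stage"]
        logger.info("running stage %s", name)
        if name == "simulate":
            table = synth.scenario_table(entry.get("seed", seed))
            scen_name = entry.get("scenario")
            if scen_name not in table:
                raise ConfigError(f"unknown scenario {scen_name!r}")
            spec = table[scen_name]
            data = synth.generate_scenario(spec, buffer)
            workspace["scenario"] = spec
            if spec.kind == "se":
                workspace["se_profiles"] = data
                if out_dir is not None:
                    write_se_profiles(data, out_dir / scen_name)
            elif spec.kind == "sv":
                workspace["sv_scans"] = data
                if out_dir is not None:
                    write_sv_scanset(data, out_dir / scen_name)
            else:
                workspace["titration"] = data
                if out_dir is not None:
                    write_titration_csv(data, out_dir / f"{scen_name}.csv")
            report["stages"][name] = {
                "scenario": scen_name,
                "seed": spec.seed,
                "params": spec.params,
            }
        elif name == "fit-se":
            if "input" in entry:
                profiles = read_se_profiles(entry["input"])
            elif "se_profiles" in workspace:
                profiles = workspace["se_profiles"]
            else:
                raise ConfigError("fit-se: no input and nothing simulated")
            vbar = entry.get(
                "vbar",
                workspace.get("scenario").params["vbar"]
                if workspace.get("scenario")
                else None,
            )
            if vbar is None:
                raise ConfigError("fit-se: vbar must be given")
            species = int(entry.get("species", 1))
            mc = bool(entry.get("mass_conservation", True))
            if species == 1:
                result = fit_one_species_global(profiles, vbar, buffer, mc)
            else:
                result = fit_two_species_global(
                    profiles, vbar, entry.get("vbar2", vbar), buffer, mc,
                    fixed_m2=entry.get("fix_m2"),
                )
            workspace["se_fit"] = result
            report["stages"][name] = _se_fit_to_dict(result)
        elif name == "fit-cs":
            if "input" in entry:
                scans = read_sv_scanset(entry["input"])
            elif "sv_scans" in workspace:
                scans = workspace["sv_scans"]
            else:
                raise ConfigError("fit-cs: no input and nothing simulated")
            vbar = entry.get(
                "vbar",
                workspace.get("scenario").params["vbar"]
                if workspace.get("scenario")
                else None,
            )
            if vbar is None:
                raise ConfigError("fit-cs: vbar must be given")
            grid = default_s_grid(
                entry.get("s_min", 0.2),
                entry.get("s_max", 12.0),
                entry.get("s_points", 100),
            )
            dist = fit_cs(
                scans, buffer, vbar, s_grid=grid,
                frictional_ratio=entry.get("ff0", 1.2),
                confidence=entry.get("confidence", 0.68),
            )
            workspace["cs_dist"] = dist
            if out_dir is not None:
                write_cs_distribution(dist, out_dir / "cs_distribution.csv")
            report["stages"][name] = {
                "weight_average_s": weight_average_s(dist),
                "fit_rmsd": dist.fit_rmsd,
                "regularization_alpha": dist.regularization_alpha,
            }
        elif name == "stoich":
            if "fitted" in entry:
                fitted, se = float(entry["fitted"]), float(entry["se"])
            elif "se_fit" in workspace:
                fitted, se = workspace["se_fit"].masses[0]
            else:
                raise ConfigError("stoich: no fitted mass available")
            rules = (
                load_rules_yaml(entry["rules"])
                if "rules" in entry
                else synth_reference_rules()
            )
            bounds = entry.get("bounds", synth_reference_bounds())
            matches = enumerate_matches(
                fitted, se, list(registry.values()), bounds, rules,
                window_k=float(entry.get("k", 2.0)),
            )
            table = [
                {
                    "composition": m.composition.formula(),
                    "predicted_mass": m.predicted_mass,
                    "deviation": m.deviation,
                    "within_window": m.within_window,
                }
                for m in matches
            ]
            workspace["stoich"] = matches
            report["stages"][name] = {
                "fitted_mass": fitted,
                "standard_error": se,
                "matches": table,
            }
        elif name == "titration":
            if "input" in entry:
                series = read_titration_csv(
                    entry["input"], entry.get("reference")
                )
            elif "titration" in workspace:
                series = workspace["titration"]
            else:
                raise ConfigError("titration: no input and nothing simulated")
            norm = normalize_series(series)
            onset = detect_onset(
                norm, min_points_per_segment=int(entry.get("min_seg", 4))
            )
            report["stages"][name] = {
                "onset_ratio": onset.onset_ratio,
                "detected": onset.detected,
                "pre_slope": onset.pre_slope,
                "post_slope": onset.post_slope,
                "f_statistic": onset.f_statistic,
            }
        else:  # pragma: no cover — guarded by validation above
            raise ConfigError(f"unknown stage {name!r}")

    if out_dir is not None:
        write_report(report, out_dir / "report.json")
    return report


def synth_reference_bounds() -> dict[str, int]:
    """Copy-number caps for the RecO/RecR/SSB-Ct/(dT)L candidate lattice."""
    return {"RecO": 2, "RecR": 4, "SSB-Ct": 2, "Cy3-dT15": 2, "Cy3-dT35": 1}


def synth_reference_rules() -> list[CopyRule]:
    """Biological copy-number rules: RecR in dimers/tetramers, one peptide
    per RecO protomer at most."""
    return [
        CopyRule(component="RecR", allowed=(0, 2, 4)),
        CopyRule(component="SSB-Ct", op="<=", other="RecO"),
    ]
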