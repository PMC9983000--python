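"""Configuration, file I/O, and synthetic-mixture fixtures.

Configuration files are YAML with *explicit unit strings* for every
physical quantity (``"7 V"``, ``"1 us"``, ``"0.2 mm"``): the instrument
description mixes volts, microseconds and millimetres, and silent unit
mistakes are the dominant implementation risk, so bare numbers are rejected
for dimensioned fields.

Cubes persist either as HDF5 (bit-exact) or as a wide CSV with the metadata
in ``#``-prefixed JSON header lines; 2D maps as sparse triplet CSV.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .calib2d import CalibrationModel, Spectrum2D
from .errors import GenerationError, ParseError
from .ftproc import Peak
from .kinematics import PrecursorSpecies, TofInstrumentConfig
from .patterns import FragmentationPattern, modulation_frequency_tof
from .sector_engine import SectorConfig, modulation_frequency_sector
from .tof_engine import ScanSchedule, TransientCube

__all__ = [
    "parse_quantity",
    "generate_mixture",
    "write_cube",
    "read_cube",
    "write_peaks",
    "write_spectrum2d",
    "read_spectrum2d",
    "write_calibration",
    "read_calibration",
    "RunConfig",
    "load_run_config",
    "config_hash",
]

# ---------------------------------------------------------------------------
# unit-aware quantity parsing

_UNIT_TABLE = {
    "voltage": {"V": 1.0, "kV": 1e3, "mV": 1e-3},
    "length": {"m": 1.0, "mm": 1e-3, "um": 1e-6, "nm": 1e-9},
    "time": {"s": 1.0, "ms": 1e-3, "us": 1e-6, "ns": 1e-9},
    "mz": {"Th": 1.0},
    "frequency": {"Hz": 1.0, "kHz": 1e3, "MHz": 1e6},
}

_QTY_RE = re.compile(r"^\s*([+-]?\d+(?:\.\d*)?(?:[eE][+-]?\d+)?)\s*([A-Za-z]+)\s*$")


def parse_quantity(text, kind: str) -> float:
    """Parse ``"<number> <unit>"`` into SI for the given unit kind.

    The unit whitelist is strict: a bare number, an unknown unit, or a unit
    of the wrong kind all raise :class:`ParseError`.
    """
    if kind not in _UNIT_TABLE:
        raise ParseError(f"unknown quantity kind {kind!r}")
    if not isinstance(text, str):
        raise ParseError(
            f"{kind} values must be unit strings like '7 V', got {text!r}"
        )
    m = _QTY_RE.match(text)
    if not m:
        raise ParseError(f"cannot parse quantity {text!r} (expected '<number> <unit>')")
    value, unit = m.groups()
    table = _UNIT_TABLE[kind]
    if unit not in table:
        raise ParseError(
            f"unit {unit!r} is not a {kind} unit (allowed: {sorted(table)})"
        )
    return float(value) * table[unit]


# ---------------------------------------------------------------------------
# synthetic mixtures

def generate_mixture(
    seed: int,
    n_precursors: int,
    mz_range: tuple[float, float] = (500.0, 2500.0),
    fragments_per_precursor_range: tuple[int, int] = (3, 6),
    min_frequency_separation: float = 3.0,
    *,
    config=None,
    pattern: Optional[FragmentationPattern] = None,
    schedule: Optional[ScanSchedule] = None,
    variant: str = "tof",
    total_branching: float = 0.9,
    max_attempts: int = 100000,
) -> list[PrecursorSpecies]:
    """Seeded random mixture whose modulation frequencies are resolvable.

    Precursor m/z values are drawn uniformly in ``mz_range`` subject to (a)
    the modulation frequency under the active configuration staying below
    the Nyquist limit of 0.5 cycles/scan and (b) all pairwise frequency
    separations being at least ``min_frequency_separation`` FWHM of the
    rectangular-window line shape (``1.2067 / n_scans`` cycles/scan).
    Fragment m/z values are uniform in ``(50 Th, precursor m/z)`` with
    branching ratios summing to ``total_branching``.

    Raises
    ------
    GenerationError
        If the separation constraint cannot be satisfied in
        ``max_attempts`` draws.
    """
    if n_precursors < 0:
        raise GenerationError("n_precursors must be >= 0")
    if not 0 < mz_range[0] < mz_range[1]:
        raise GenerationError(f"bad m/z range {mz_range}")
    if n_precursors == 0:
        return []
    if pattern is None:
        raise GenerationError("generate_mixture needs the active pattern")

    if variant == "tof":
        if config is None:
            config = TofInstrumentConfig()
        if schedule is None:
            schedule = ScanSchedule.zone_splitting(config)
        n_scans = schedule.n_scans
        step = schedule.delay_increment

        def freq_cps(mz: float) -> float:
            return modulation_frequency_tof(pattern, mz, 1, config.v_kick) * step

    elif variant == "sector":
        if not isinstance(config, SectorConfig):
            raise GenerationError("sector variant needs a SectorConfig")
        n_scans = config.n_runs
        step = config.pulse_step

        def freq_cps(mz: float) -> float:
            return modulation_frequency_sector(pattern, mz, config) * step

    else:
        raise GenerationError(f"unknown variant {variant!r}")

    fwhm = 1.2067 / n_scans
    rng = np.random.default_rng(seed)
    lo_f, hi_f = fragments_per_precursor_range
    chosen_mz: list[float] = []
    chosen_f: list[float] = []
    attempts = 0
    while len(chosen_mz) < n_precursors:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"could not place {n_precursors} precursors with "
                f"{min_frequency_separation}-FWHM separation in {max_attempts} attempts"
            )
        mz = float(rng.uniform(*mz_range))
        f = freq_cps(mz)
        if f >= 0.5 - fwhm:
            continue
        if any(abs(f - g) < min_frequency_separation * fwhm for g in chosen_f):
            continue
        chosen_mz.append(mz)
        chosen_f.append(f)

    mixture = []
    for mz in chosen_mz:
        n_frag = int(rng.integers(lo_f, hi_f + 1))
        frag_mz = rng.uniform(50.0, mz, size=n_frag)
        branching = total_branching * rng.dirichlet(np.ones(n_frag))
        mixture.append(
            PrecursorSpecies(
                mz=mz,
                charge=1,
                abundance=float(rng.uniform(0.2, 1.0)),
                fragments=tuple(zip(frag_mz.tolist(), branching.tolist())),
            )
        )
    return mixture


# ---------------------------------------------------------------------------
# cube persistence

_CSV_MAGIC = "# spatial2dms-cube v1"


def write_cube(cube: TransientCube, path, format: Optional[str] = None) -> None:
    """Persist a cube as HDF5 (``.h5``/``.hdf5``, bit-exact) or wide CSV."""
    path = Path(path)
    fmt = format or ("hdf5" if path.suffix in (".h5", ".hdf5") else "csv")
    if fmt == "hdf5":
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("intensity", data=cube.intensity)
            fh.create_dataset("scan_axis_s", data=cube.scan_axis)
            fh.create_dataset("channel_mz", data=cube.channel_mz)
            fh.create_dataset(
                "channel_kind",
                data=np.array([k.encode() for k in cube.channel_kind]),
            )
            fh.attrs["metadata_json"] = json.dumps(cube.metadata)
    elif fmt == "csv":
        with open(path, "w") as fh:
            fh.write(_CSV_MAGIC + "\n")
            fh.write("# metadata: " + json.dumps(cube.metadata) + "\n")
            fh.write("# channel_kind: " + ",".join(cube.channel_kind) + "\n")
            fh.write(
                "scan_axis_s,"
                + ",".join(f"{m:.17g}" for m in cube.channel_mz)
                + "\n"
            )
            for k in range(cube.n_scans):
                fh.write(
                    f"{cube.scan_axis[k]:.17g},"
                    + ",".join(f"{v:.17g}" for v in cube.intensity[k])
                    + "\n"
                )
    else:
        raise ParseError(f"unknown cube format {fmt!r}")


def read_cube(path) -> TransientCube:
    """Read a cube written by :func:`write_cube` (format inferred)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as fh:
            return TransientCube(
                intensity=fh["intensity"][()],
                scan_axis=fh["scan_axis_s"][()],
                channel_mz=fh["channel_mz"][()],
                channel_kind=np.array(
                    [k.decode() for k in fh["channel_kind"][()]]
                ),
                metadata=json.loads(fh.attrs["metadata_json"]),
            )
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != _CSV_MAGIC:
        raise ParseError(f"{path}:1: not a spatial2dms cube CSV")
    try:
        metadata = json.loads(lines[1].removeprefix("# metadata: "))
        kinds = np.array(lines[2].removeprefix("# channel_kind: ").split(","))
        header = lines[3].split(",")
        if header[0] != "scan_axis_s":
            raise ParseError(f"{path}:4: bad header")
        channel_mz = np.array([float(x) for x in header[1:]])
        rows = []
        axis = []
        for ln, line in enumerate(lines[4:], start=5):
            if not line:
                continue
            cells = line.split(",")
            if len(cells) != channel_mz.size + 1:
                raise ParseError(
                    f"{path}:{ln}: expected {channel_mz.size + 1} cells, "
                    f"got {len(cells)}"
                )
            axis.append(float(cells[0]))
            rows.append([float(c) for c in cells[1:]])
    except ParseError:
        raise
    except (IndexError, ValueError, json.JSONDecodeError) as exc:
        raise ParseError(f"{path}: malformed cube CSV: {exc}") from exc
    if len(rows) < 2:
        raise ParseError(f"{path}: truncated cube (fewer than 2 scans)")
    return TransientCube(
        intensity=np.array(rows),
        scan_axis=np.array(axis),
        channel_mz=channel_mz,
        channel_kind=kinds,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# peak list / 2D map / calibration persistence

def write_peaks(
    peaks: Sequence[tuple[float, Peak]], path
) -> None:
    """Write ``(channel_mz, Peak)`` pairs as the standard peak-list CSV."""
    df = pd.DataFrame(
        [
            {
                "channel_mz": mz,
                "centroid_cycles_per_scan": p.frequency,
                "height": p.height,
                "fwhm": p.fwhm,
                "rp_f": p.resolving_power_f,
                "rp_mz": p.resolving_power_mz,
            }
            for mz, p in peaks
        ]
    )
    df.to_csv(path, index=False)


def write_spectrum2d(spectrum: Spectrum2D, path) -> None:
    spectrum.to_dataframe().to_csv(path, index=False)


def read_spectrum2d(path) -> Spectrum2D:
    try:
        df = pd.read_csv(path)
        return Spectrum2D(
            precursor_mz=df["precursor_mz"].to_numpy(),
            fragment_mz=df["fragment_mz"].to_numpy(),
            intensity=df["intensity"].to_numpy(),
        )
    except (KeyError, ValueError) as exc:
        raise ParseError(f"{path}: malformed 2D map CSV: {exc}") from exc


def write_calibration(model: CalibrationModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "D": model.D,
                "C": model.C,
                "variant": model.variant,
                "frequency_unit": model.frequency_unit,
                "residual_rms": model.residual_rms,
                "n_points": model.n_points,
            },
            fh,
            indent=2,
        )


def read_calibration(path) -> CalibrationModel:
    try:
        with open(path) as fh:
            payload = json.load(fh)
        return CalibrationModel(**payload)
    except (json.JSONDecodeError, TypeError, KeyError) as exc:
        raise ParseError(f"{path}: malformed calibration JSON: {exc}") from exc


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """A fully resolved simulation run description."""

    variant: str
    mode: str
    seed: Optional[int]
    instrument: object  # TofInstrumentConfig | SectorConfig
    pattern: FragmentationPattern
    schedule: Optional[ScanSchedule]
    mixture: list[PrecursorSpecies]
    n_ions: int = 10000
    raw: dict = field(default_factory=dict)

    @property
    def hash(self) -> str:
        return config_hash(self.raw)


def config_hash(raw: dict) -> str:
    """Stable short hash of a raw configuration mapping."""
    canon = json.dumps(raw, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _require(block: dict, key: str, context: str):
    if key not in block:
        raise ParseError(f"missing {context} key {key!r}")
    return block[key]


def _build_pattern(block: dict) -> FragmentationPattern:
    kind = block.get("kind", "dual_slit")
    if kind == "custom_tabulated":
        return FragmentationPattern.from_csv(
            _require(block, "table_csv", "pattern"),
            zone_length=(
                parse_quantity(block["zone_length"], "length")
                if "zone_length" in block
                else None
            ),
        )
    return FragmentationPattern(
        kind=kind,
        fringe_spacing=parse_quantity(_require(block, "fringe_spacing", "pattern"), "length"),
        zone_length=parse_quantity(_require(block, "zone_length", "pattern"), "length"),
        phase_offset=parse_quantity(block.get("phase_offset", "0 m"), "length"),
        envelope=block.get("envelope"),
    )


def _build_species(entry: dict) -> PrecursorSpecies:
    return PrecursorSpecies(
        mz=parse_quantity(_require(entry, "mz", "species"), "mz"),
        charge=int(entry.get("charge", 1)),
        abundance=float(entry.get("abundance", 1.0)),
        fragments=tuple(
            (parse_quantity(fmz, "mz"), float(br))
            for fmz, br in entry.get("fragments", [])
        ),
    )


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    See the repository README for the schema; every dimensioned field is a
    unit string.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: top level must be a mapping")

    variant = _require(raw, "variant", "run")
    if variant not in ("tof", "sector"):
        raise ParseError(f"unknown variant {variant!r}")
    mode = raw.get("mode", "deterministic")
    if mode not in ("deterministic", "stochastic"):
        raise ParseError(f"unknown mode {mode!r}")
    seed = raw.get("seed")
    if mode == "stochastic" and seed is None:
        raise ParseError("stochastic mode requires a seed")

    inst = raw.get("instrument", {})
    pattern = _build_pattern(_require(raw, "pattern", "run"))

    schedule: Optional[ScanSchedule] = None
    if variant == "tof":
        instrument = TofInstrumentConfig(
            v_kick=parse_quantity(inst.get("v_kick", "7 V"), "voltage"),
            v_repeller=parse_quantity(inst.get("v_repeller", "1000 V"), "voltage"),
            v_extractor=parse_quantity(inst.get("v_extractor", "905 V"), "voltage"),
            v_lens=parse_quantity(inst.get("v_lens", "914 V"), "voltage"),
            flight_length=parse_quantity(inst.get("flight_length", "1 m"), "length"),
            zone_start=parse_quantity(inst.get("zone_start", "5 mm"), "length"),
            zone_length=parse_quantity(inst.get("zone_length", "36 mm"), "length"),
        )
        sched_block = raw.get("schedule", {})
        if "delay_increment" in sched_block:
            schedule = ScanSchedule(
                delay_increment=parse_quantity(sched_block["delay_increment"], "time"),
                n_scans=int(sched_block.get("n_scans", 32768)),
                initial_delay=parse_quantity(
                    sched_block.get("initial_delay", "0 s"), "time"
                ),
            )
        else:
            schedule = ScanSchedule.zone_splitting(
                instrument,
                n_scans=int(sched_block.get("n_scans", 32768)),
                mz_ref=float(sched_block.get("mz_ref", 1000.0)),
            )
    else:
        instrument = SectorConfig(
            deflection_potential=parse_quantity(
                inst.get("deflection_potential", "3 V"), "voltage"
            ),
            gap=parse_quantity(inst.get("gap", "10 mm"), "length"),
            pulse_step=parse_quantity(inst.get("pulse_step", "1 us"), "time"),
            n_runs=int(inst.get("n_runs", 8192)),
            entry_potential=parse_quantity(
                inst.get("entry_potential", "1000 V"), "voltage"
            ),
            entry_angle=float(inst.get("entry_angle_rad", 0.0)),
            drift_distance=parse_quantity(inst.get("drift_distance", "25 mm"), "length"),
            zone_pass_time=(
                parse_quantity(inst["zone_pass_time"], "time")
                if "zone_pass_time" in inst
                else None
            ),
        )

    mix_block = _require(raw, "mixture", "run")
    source = mix_block.get("source", "inline")
    if source == "inline":
        mixture = [_build_species(e) for e in _require(mix_block, "species", "mixture")]
    elif source == "fixture":
        gen_seed = mix_block.get("seed", seed)
        if gen_seed is None:
            raise ParseError("fixture mixture requires a seed")
        mz_range = tuple(
            parse_quantity(x, "mz") for x in mix_block.get("mz_range", ["500 Th", "2500 Th"])
        )
        mixture = generate_mixture(
            seed=int(gen_seed),
            n_precursors=int(_require(mix_block, "n_precursors", "mixture")),
            mz_range=mz_range,  # type: ignore[arg-type]
            fragments_per_precursor_range=tuple(
                mix_block.get("fragments_per_precursor", [3, 6])
            ),
            min_frequency_separation=float(
                mix_block.get("min_frequency_separation", 3.0)
            ),
            config=instrument,
            pattern=pattern,
            schedule=schedule,
            variant=variant,
        )
    else:
        raise ParseError(f"unknown mixture source {source!r}")

    return RunConfig(
        variant=variant,
        mode=mode,
        seed=seed,
        instrument=instrument,
        pattern=pattern,
        schedule=schedule,
        mixture=mixture,
        n_ions=int(raw.get("n_ions", 10000)),
        raw=raw,
    )
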