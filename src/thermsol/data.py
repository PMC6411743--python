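"""Shared data model and table IO.

Everything downstream speaks one long (tidy) quantification format: one row
per (protein, sample) with the sample's full annotation held separately in
:class:`SampleMeta`.  Wide input files (one column per sample) are pivoted to
long form on read.  Experiment layouts -- which (temperature, concentration,
detergent) cells each TMT plex covers -- are validated against the design
rules of the three supported experiment kinds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("thermsol")

QUPM_BINS = (2, 3, 4, 5)  # 5 encodes the capped category "5 or more"

META_COLUMNS = (
    "sample_id",
    "replicate",
    "temperature",
    "concentration_mM",
    "detergent",
    "tmt_plex",
    "tmt_label",
    "condition",
)


class LayoutError(ValueError):
    """Raised when sample metadata violates the declared experimental design."""


class ParseError(ValueError):
    """Raised when a quantification table cannot be interpreted."""


@dataclass(frozen=True)
class SampleMeta:
    """Annotation of one TMT channel in one plex.

    ``concentration_mM`` is the ligand dose in mM with 0 denoting vehicle;
    ``detergent`` is ``"NP40"``, ``"SDS"`` or ``"none"``; ``condition`` is
    ``"treated"`` or ``"vehicle"``.
    """

    sample_id: str
    replicate: int
    temperature: float
    concentration_mM: float
    detergent: str = "none"
    tmt_plex: str = ""
    tmt_label: str = ""
    condition: str = "treated"

    def __post_init__(self):
        if self.concentration_mM < 0:
            raise ValueError(f"negative concentration for sample {self.sample_id}")
        if self.replicate < 1:
            raise ValueError(f"replicate must be a positive integer ({self.sample_id})")
        if self.detergent not in ("NP40", "SDS", "none"):
            raise ValueError(f"unknown detergent {self.detergent!r} ({self.sample_id})")
        if self.condition not in ("treated", "vehicle"):
            raise ValueError(f"unknown condition {self.condition!r} ({self.sample_id})")


@dataclass
class QuantTable:
    """Long-format protein x sample quantification.

    ``df`` columns: ``protein_id``, ``sample_id``, ``value``, ``qupm``.
    ``value_kind`` declares whether values are reporter intensities, fold
    changes, or log2 fold changes.  qupm (quantified peptides per protein) is
    capped at the category "5 or more", stored as the integer 5.
    """

    df: pd.DataFrame
    value_kind: str = "intensity"

    def __post_init__(self):
        required = {"protein_id", "sample_id", "value", "qupm"}
        missing = required - set(self.df.columns)
        if missing:
            raise ParseError(f"quant table missing columns: {sorted(missing)}")
        if self.value_kind not in ("intensity", "fold_change", "log2_fold_change"):
            raise ParseError(f"unknown value_kind {self.value_kind!r}")
        dup = self.df.duplicated(["protein_id", "sample_id"])
        if dup.any():
            first = self.df.loc[dup, ["protein_id", "sample_id"]].iloc[0]
            raise ParseError(
                f"duplicate (protein, sample) entry: {first.protein_id}/{first.sample_id}"
            )
        values = self.df["value"].to_numpy()
        if not np.isfinite(values).all():
            bad = self.df.loc[~np.isfinite(values)].iloc[0]
            raise ParseError(f"non-finite value for {bad.protein_id}/{bad.sample_id}")
        if self.value_kind == "intensity" and (values < 0).any():
            bad = self.df.loc[values < 0].iloc[0]
            raise ParseError(f"negative intensity for {bad.protein_id}/{bad.sample_id}")
        if self.value_kind == "fold_change" and (values <= 0).any():
            bad = self.df.loc[values <= 0].iloc[0]
            raise ParseError(f"non-positive fold change for {bad.protein_id}/{bad.sample_id}")
        self.df = self.df.copy()
        self.df["qupm"] = bin_qupm(self.df["qupm"].to_numpy())

    @property
    def proteins(self) -> list[str]:
        return sorted(self.df["protein_id"].unique())

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample_id"].unique())


@dataclass
class ExperimentLayout:
    """Validated design of one experiment.

    ``plex_map`` maps each TMT plex identifier to the list of
    (temperature, concentration_mM, detergent) cells it covers.
    """

    kind: str
    temperatures: tuple
    concentrations_mM: tuple
    n_replicates: int
    plex_map: dict


def bin_qupm(qupm: np.ndarray) -> np.ndarray:
    """Cap quantified-peptide counts into the categories {2, 3, 4, 5+}."""
    arr = np.asarray(qupm)
    if not np.issubdtype(arr.dtype, np.number):
        raise ParseError("qupm must be numeric")
    if (arr < 2).any():
        raise ParseError("qupm must be >= 2 (proteins require two quantified peptides)")
    return np.minimum(arr.astype(int), 5)


def meta_frame(samples: Iterable[SampleMeta]) -> pd.DataFrame:
    """Tabulate sample metadata, one row per sample."""
    rows = [
        (s.sample_id, s.replicate, s.temperature, s.concentration_mM,
         s.detergent, s.tmt_plex, s.tmt_label, s.condition)
        for s in samples
    ]
    return pd.DataFrame(rows, columns=list(META_COLUMNS))


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def read_metadata(path: str | Path) -> list[SampleMeta]:
    """Read sample metadata from TSV/CSV into :class:`SampleMeta` records."""
    df = _read_table(path)
    missing = set(META_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise LayoutError(f"metadata missing columns: {sorted(missing)}")
    samples = []
    for _, row in df.iterrows():
        samples.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                replicate=int(row["replicate"]),
                temperature=float(row["temperature"]),
                concentration_mM=float(row["concentration_mM"]),
                detergent=str(row.get("detergent", "none")),
                tmt_plex=str(row.get("tmt_plex", "")),
                tmt_label=str(row.get("tmt_label", "")),
                condition=str(
                    row.get("condition",
                            "vehicle" if float(row["concentration_mM"]) == 0 else "treated")
                ),
            )
        )
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise LayoutError("duplicate sample_id in metadata")
    return samples


def read_quant_table(
    path: str | Path,
    meta_path: str | Path,
    value_kind: str = "intensity",
) -> tuple[QuantTable, list[SampleMeta]]:
    """Read a wide quantification table plus its sample metadata.

    The wide table holds ``protein_id``, optionally ``qupm``, and one numeric
    column per sample.  Every sample named in the metadata must appear as a
    column and vice versa; qupm defaults to 2 when absent.
    """
    wide = _read_table(path)
    samples = read_metadata(meta_path)
    if "protein_id" not in wide.columns:
        raise ParseError("quant table must contain a 'protein_id' column")
    sample_ids = [s.sample_id for s in samples]
    data_cols = [c for c in wide.columns if c not in ("protein_id", "qupm")]
    missing = sorted(set(sample_ids) - set(data_cols))
    if missing:
        raise LayoutError(f"metadata lists samples absent from quant table: {missing}")
    extra = sorted(set(data_cols) - set(sample_ids))
    if extra:
        raise LayoutError(f"quant table has samples without metadata: {extra}")
    qupm = wide["qupm"] if "qupm" in wide.columns else pd.Series(2, index=wide.index)
    long = wide.melt(
        id_vars=["protein_id"],
        value_vars=sample_ids,
        var_name="sample_id",
        value_name="value",
    )
    long = long.merge(
        pd.DataFrame({"protein_id": wide["protein_id"], "qupm": qupm}),
        on="protein_id",
    )
    bad = pd.to_numeric(long["value"], errors="coerce").isna()
    if bad.any():
        row = long.loc[bad].iloc[0]
        raise ParseError(
            f"non-numeric value for protein {row.protein_id}, sample {row.sample_id}"
        )
    long["value"] = long["value"].astype(float)
    table = QuantTable(long[["protein_id", "sample_id", "value", "qupm"]], value_kind)
    log.info("read %d proteins x %d samples from %s",
             len(table.proteins), len(samples), path)
    return table, samples


def validate_layout(samples: Sequence[SampleMeta], kind: str) -> ExperimentLayout:
    """Check sample metadata against the design rules of one experiment kind.

    ``TPP_2D``: every plex spans exactly two *adjacent* temperatures of the
    experiment's gradient, each covering the full concentration series.
    ``SPP``: every plex holds nine NP40 samples (one vehicle + eight doses)
    and exactly one SDS vehicle.  ``TPP_TR``: every plex covers the full
    temperature gradient at a single condition.
    """
    kind = kind.upper().replace("-", "_")
    if kind not in ("TPP_TR", "TPP_2D", "SPP"):
        raise LayoutError(f"unknown experiment kind {kind!r}")
    if not samples:
        raise LayoutError("no samples in metadata")

    temperatures = tuple(sorted({s.temperature for s in samples}))
    concentrations = tuple(sorted({s.concentration_mM for s in samples}))
    replicates = sorted({s.replicate for s in samples})
    plex_map: dict[str, list] = {}
    for s in samples:
        plex_map.setdefault(s.tmt_plex, []).append(
            (s.temperature, s.concentration_mM, s.detergent)
        )

    if kind == "TPP_2D":
        for plex, cells in plex_map.items():
            temps = sorted({t for t, _, _ in cells})
            if len(temps) != 2:
                raise LayoutError(
                    f"2D plex {plex!r} spans {len(temps)} temperatures, expected 2"
                )
            i, j = temperatures.index(temps[0]), temperatures.index(temps[1])
            if j != i + 1:
                raise LayoutError(
                    f"2D plex {plex!r} spans non-adjacent temperatures {temps}"
                )
            for t in temps:
                concs = sorted({c for tt, c, _ in cells if tt == t})
                if tuple(concs) != concentrations:
                    raise LayoutError(
                        f"2D plex {plex!r} misses concentrations at {t} degC: "
                        f"has {concs}, expected {list(concentrations)}"
                    )
        if 0.0 not in concentrations:
            raise LayoutError("2D layout requires a vehicle (0 mM) at every temperature")

    elif kind == "SPP":
        for plex, cells in plex_map.items():
            np40 = [(t, c) for t, c, det in cells if det == "NP40"]
            sds = [(t, c) for t, c, det in cells if det == "SDS"]
            if len(sds) != 1 or sds[0][1] != 0.0:
                raise LayoutError(
                    f"SPP plex {plex!r} must contain exactly one SDS vehicle, "
                    f"found {len(sds)}"
                )
            np40_doses = sorted(c for _, c in np40)
            if len(np40) != 9 or np40_doses[0] != 0.0 or len(set(np40_doses)) != 9:
                raise LayoutError(
                    f"SPP plex {plex!r} must contain nine NP40 samples "
                    f"(vehicle + 8 distinct doses), found doses {np40_doses}"
                )

    else:  # TPP_TR
        for plex, cells in plex_map.items():
            temps = sorted({t for t, _, _ in cells})
            if tuple(temps) != temperatures:
                raise LayoutError(
                    f"TR plex {plex!r} does not cover the full temperature gradient"
                )
            conds = {c for _, c, _ in cells}
            if len(conds) != 1:
                raise LayoutError(f"TR plex {plex!r} mixes conditions {sorted(conds)}")

    layout = ExperimentLayout(
        kind=kind,
        temperatures=temperatures,
        concentrations_mM=concentrations,
        n_replicates=len(replicates),
        plex_map=plex_map,
    )
    log.info("validated %s layout: %d plexes, %d temperatures, %d concentrations",
             kind, len(plex_map), len(temperatures), len(concentrations))
    return layout


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a results table as TSV with a deterministic column order.

    Round-tripping through :func:`read_results` reproduces all numeric values
    to within 1e-9 relative tolerance (full float repr is written).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    results.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
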