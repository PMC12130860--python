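"""Readers and writers for trio tables, species panels, and newick trees.

Trio tables are delimited text files with one parent-offspring trio per row:
the parental ages at conception, the (correction-factor adjusted, hence
possibly non-integer) de novo mutation counts, the subset of mutations with
parent-of-origin phase, and the callable haploid genome length used by the
variant-calling pipeline.  Species panels carry the life-history and rate
columns used by the cross-species regressions.  All ages are stored in years;
a reader flag converts ages given in weeks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

logger = logging.getLogger(__name__)

#: Mean number of Gregorian calendar weeks in a year.
WEEKS_PER_YEAR = 52.1775

#: Canonical trio-table column names.
TRIO_COLUMNS = (
    "trio_id",
    "dataset",
    "paternal_age",
    "maternal_age",
    "n_mut",
    "n_pat_phased",
    "n_mat_phased",
    "n_unphased",
    "callable_bp",
)

#: Canonical species-table column names (``pi`` optional).
SPECIES_COLUMNS = ("species", "g", "P", "mu", "pi", "source")

#: Tolerance for the phased + unphased == total bookkeeping identity.
PHASE_SUM_TOL = 1e-6


class TableFormatError(ValueError):
    """Malformed or inconsistent row in an input table."""


@dataclass(frozen=True)
class TrioRecord:
    """One trio: parental ages, mutation counts and callable genome length.

    Counts are real-valued because source studies apply multiplicative
    false-positive/false-negative corrections to raw calls.
    """

    trio_id: str
    dataset_label: str
    paternal_age: float
    maternal_age: float
    n_mut_total: float
    n_paternal_phased: float
    n_maternal_phased: float
    n_unphased: float
    callable_haploid_bp: float

    def __post_init__(self) -> None:
        if not self.paternal_age > 0:
            raise TableFormatError(
                f"trio {self.trio_id!r}: paternal_age must be > 0, got {self.paternal_age}"
            )
        if not self.maternal_age > 0:
            raise TableFormatError(
                f"trio {self.trio_id!r}: maternal_age must be > 0, got {self.maternal_age}"
            )
        if not self.callable_haploid_bp > 0:
            raise TableFormatError(
                f"trio {self.trio_id!r}: callable_bp must be > 0, got {self.callable_haploid_bp}"
            )
        for name in ("n_mut_total", "n_paternal_phased", "n_maternal_phased", "n_unphased"):
            if getattr(self, name) < 0:
                raise TableFormatError(
                    f"trio {self.trio_id!r}: {name} must be >= 0, got {getattr(self, name)}"
                )
        phase_sum = self.n_paternal_phased + self.n_maternal_phased + self.n_unphased
        if not math.isclose(phase_sum, self.n_mut_total, rel_tol=0.0, abs_tol=PHASE_SUM_TOL):
            raise TableFormatError(
                f"trio {self.trio_id!r}: phased + unphased counts ({phase_sum}) "
                f"differ from total ({self.n_mut_total})"
            )


@dataclass(frozen=True)
class SpeciesRecord:
    """One species' life-history and mutation-rate summary.

    ``generation_time`` (g) is the mean age at reproduction; ``puberty_age``
    (P) the age at puberty / first reproduction; ``mu_per_generation`` the
    per-site per-generation germline mutation rate; ``pi`` nucleotide
    diversity, used to derive the effective population size.
    """

    species: str
    generation_time: float
    puberty_age: float
    mu_per_generation: float | None = None
    pi: float | None = None
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.generation_time > 0:
            raise TableFormatError(
                f"species {self.species!r}: generation time must be > 0, "
                f"got {self.generation_time}"
            )
        if self.puberty_age < 0:
            raise TableFormatError(
                f"species {self.species!r}: puberty age must be >= 0, got {self.puberty_age}"
            )


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a tab- or comma-delimited text table, empty-safe."""
    import csv

    path = Path(path)
    try:
        return pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, csv.Error):
        if path.stat().st_size == 0 or not path.read_text().strip():
            return pd.DataFrame()
        raise TableFormatError(f"{path}: could not determine table delimiter")


def _rename(df: pd.DataFrame, dialect: Mapping[str, str] | None) -> pd.DataFrame:
    if dialect:
        df = df.rename(columns=dict(dialect))
    return df


def read_trio_table(
    path: str | Path,
    *,
    ages_in_weeks: bool = False,
    dialect: Mapping[str, str] | None = None,
) -> list[TrioRecord]:
    """Read a trio table into validated :class:`TrioRecord` objects.

    Parameters
    ----------
    path:
        Tab- or comma-delimited file with a header row using the canonical
        column names in :data:`TRIO_COLUMNS`.  The phasing columns may be
        absent, in which case every mutation is treated as unphased.
    ages_in_weeks:
        If True, parental ages in the file are in weeks and are divided by
        :data:`WEEKS_PER_YEAR` on ingestion.
    dialect:
        Optional mapping from this file's column headers to the canonical
        names, for tables from studies with other layouts.
    """
    df = _rename(_read_delimited(path), dialect)
    if df.empty:
        logger.warning("trio table %s is empty", path)
        return []
    required = {"trio_id", "paternal_age", "maternal_age", "n_mut", "callable_bp"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing required columns {sorted(missing)}")
    has_phase = {"n_pat_phased", "n_mat_phased"} <= set(df.columns)
    records = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        r = row._asdict()
        scale = 1.0 / WEEKS_PER_YEAR if ages_in_weeks else 1.0
        total = float(r["n_mut"])
        if has_phase:
            up = float(r["n_pat_phased"])
            um = float(r["n_mat_phased"])
            ux = float(r.get("n_unphased", total - up - um))
        else:
            up = um = 0.0
            ux = total
        try:
            records.append(
                TrioRecord(
                    trio_id=str(r["trio_id"]),
                    dataset_label=str(r.get("dataset", "")),
                    paternal_age=float(r["paternal_age"]) * scale,
                    maternal_age=float(r["maternal_age"]) * scale,
                    n_mut_total=total,
                    n_paternal_phased=up,
                    n_maternal_phased=um,
                    n_unphased=ux,
                    callable_haploid_bp=float(r["callable_bp"]),
                )
            )
        except (TableFormatError, TypeError) as err:
            raise TableFormatError(f"{path} line {line_no}: {err}") from err
    return records


def write_trio_table(records: Iterable[TrioRecord], path: str | Path) -> None:
    """Write trio records as canonical TSV; numerics keep 10+ significant digits."""
    rows = [
        {
            "trio_id": r.trio_id,
            "dataset": r.dataset_label,
            "paternal_age": r.paternal_age,
            "maternal_age": r.maternal_age,
            "n_mut": r.n_mut_total,
            "n_pat_phased": r.n_paternal_phased,
            "n_mat_phased": r.n_maternal_phased,
            "n_unphased": r.n_unphased,
            "callable_bp": r.callable_haploid_bp,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=TRIO_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def trios_to_frame(records: Sequence[TrioRecord]) -> pd.DataFrame:
    """Vectorized view of a trio list as a DataFrame (canonical columns)."""
    return pd.DataFrame(
        {
            "trio_id": [r.trio_id for r in records],
            "dataset": [r.dataset_label for r in records],
            "paternal_age": [r.paternal_age for r in records],
            "maternal_age": [r.maternal_age for r in records],
            "n_mut": [r.n_mut_total for r in records],
            "n_pat_phased": [r.n_paternal_phased for r in records],
            "n_mat_phased": [r.n_maternal_phased for r in records],
            "n_unphased": [r.n_unphased for r in records],
            "callable_bp": [r.callable_haploid_bp for r in records],
        }
    )


def read_species_table(
    path: str | Path, *, dialect: Mapping[str, str] | None = None
) -> list[SpeciesRecord]:
    """Read a species panel into :class:`SpeciesRecord` objects.

    Expects canonical columns ``species, g, P, mu, pi, source`` (``mu``,
    ``pi`` and ``source`` optional); extra columns are ignored.
    """
    df = _rename(_read_delimited(path), dialect)
    if df.empty:
        logger.warning("species table %s is empty", path)
        return []
    if not {"species", "g", "P"} <= set(df.columns):
        raise TableFormatError(f"{path}: species table needs columns species, g, P")
    records = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        r = row._asdict()
        pi = r.get("pi")
        try:
            records.append(
                SpeciesRecord(
                    species=str(r["species"]),
                    generation_time=float(r["g"]),
                    puberty_age=float(r["P"]),
                    mu_per_generation=(None if "mu" not in r else float(r["mu"])),
                    pi=(None if pi is None or pd.isna(pi) else float(pi)),
                    source_label=str(r.get("source", "")),
                )
            )
        except (TableFormatError, TypeError) as err:
            raise TableFormatError(f"{path} line {line_no}: {err}") from err
    return records


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a rooted newick tree (path or newick string).

    Underscores in unquoted labels become spaces, following the newick
    standard, so file taxon ``Olive_baboon`` matches species ``Olive baboon``.
    """
    try:
        if isinstance(source, (str,)) and source.lstrip().startswith("("):
            tree = dendropy.Tree.get(data=source, schema="newick")
        else:
            tree = dendropy.Tree.get(path=str(source), schema="newick")
    except Exception as err:  # dendropy raises several parser error types
        raise ValueError(f"could not parse newick input: {err}") from err
    return tree


# ---------------------------------------------------------------------------
# Packaged fixtures


def load_table1() -> pd.DataFrame:
    """The packaged ten-row species panel of regression-based rate estimates.

    Columns: species, mu_E (per site per generation), mu_OS (per site per
    year), P, g (years), mu (per site per generation), source.  Two baboon
    and two aye-aye rows are present, one per source study.
    """
    with resources.files("germdecomp").joinpath("data/table1_species.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_reference_tree() -> dendropy.Tree:
    """Approximate 8-taxon mammal chronogram (branch lengths in Myr).

    This is a synthetic stand-in assembled from consensus mammalian
    divergence-time estimates; it matches the species names of
    :func:`load_table1` and is used for the packaged cross-species fits.
    """
    text = (
        resources.files("germdecomp")
        .joinpath("data/mammal8_tree_synthetic.nwk")
        .read_text()
    )
    return read_newick(text)
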