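"""Readers and writers for the pipeline's text formats.

One TSV dialect throughout: tab-separated, a single header row, '#' comment
lines, ISO-8601 dates, empty field = unknown.  Residency intervals are a
semicolon-separated list of ``start..end`` items with an open end written as
``start..``.  Genotype likelihoods use the beagle-style 3-columns-per-
individual text format (gzip-transparent); a missing site is the triple
``0 0 0``, and non-normalized triples are renormalized with a warning.
All readers report malformed lines with file and line number.
"""

from __future__ import annotations

import csv
import datetime as dt
import gzip
import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .demography import PAIR_TABLE_COLUMNS, IndividualRecord, ParentageRecord
from .pedigree import Pedigree
from .relatedness import GenotypeLikelihoodMatrix

logger = logging.getLogger(__name__)

RESIDENCY_COLUMNS = (
    "id",
    "sex",
    "birth_date",
    "birth_date_known",
    "death_date",
    "natality",
    "immigration_date",
    "emigration_date",
    "residency",
    "in_genetic_dataset",
)


class FileFormatError(ValueError):
    """A malformed input file, reported with file, line and field."""

    def __init__(self, path, line: Optional[int], message: str):
        self.path = str(path)
        self.line = line
        loc = f"{path}:{line}" if line is not None else str(path)
        super().__init__(f"{loc}: {message}")


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _parse_date(value: str, path, line: int) -> Optional[dt.date]:
    if value == "":
        return None
    try:
        return dt.date.fromisoformat(value)
    except ValueError:
        raise FileFormatError(path, line, f"invalid ISO date {value!r}") from None


def _fmt_date(d: Optional[dt.date]) -> str:
    return d.isoformat() if d is not None else ""


def _parse_bool(value: str, path, line: int) -> bool:
    if value in ("1", "true", "True"):
        return True
    if value in ("0", "false", "False"):
        return False
    raise FileFormatError(path, line, f"invalid boolean {value!r}")


# ---------------------------------------------------------------- residency


def write_residency(records: Iterable[IndividualRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(RESIDENCY_COLUMNS)
        for r in records:
            residency = ";".join(
                f"{_fmt_date(s)}..{_fmt_date(e)}" for s, e in r.residency
            )
            w.writerow(
                [
                    r.id,
                    r.sex,
                    _fmt_date(r.birth_date),
                    int(r.birth_date_known),
                    _fmt_date(r.death_date),
                    r.natality,
                    _fmt_date(r.immigration_date),
                    _fmt_date(r.emigration_date),
                    residency,
                    int(r.in_genetic_dataset),
                ]
            )


def read_residency(path) -> list[IndividualRecord]:
    records = []
    with _open_text(path) as fh:
        header: Optional[list[str]] = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if tuple(header) != RESIDENCY_COLUMNS:
                    raise FileFormatError(
                        path, lineno, f"unexpected header {header!r}"
                    )
                continue
            if len(fields) != len(RESIDENCY_COLUMNS):
                raise FileFormatError(
                    path, lineno, f"expected {len(RESIDENCY_COLUMNS)} fields, got {len(fields)}"
                )
            row = dict(zip(RESIDENCY_COLUMNS, fields))
            residency = []
            if row["residency"]:
                for item in row["residency"].split(";"):
                    if ".." not in item:
                        raise FileFormatError(
                            path, lineno, f"invalid residency interval {item!r}"
                        )
                    s, e = item.split("..", 1)
                    residency.append(
                        (
                            _parse_date(s, path, lineno),
                            _parse_date(e, path, lineno),
                        )
                    )
            try:
                records.append(
                    IndividualRecord(
                        id=row["id"],
                        sex=row["sex"],
                        birth_date=_parse_date(row["birth_date"], path, lineno),
                        birth_date_known=_parse_bool(row["birth_date_known"], path, lineno),
                        death_date=_parse_date(row["death_date"], path, lineno),
                        natality=row["natality"],
                        immigration_date=_parse_date(row["immigration_date"], path, lineno),
                        emigration_date=_parse_date(row["emigration_date"], path, lineno),
                        residency=residency,
                        in_genetic_dataset=_parse_bool(row["in_genetic_dataset"], path, lineno),
                    )
                )
            except ValueError as exc:
                raise FileFormatError(path, lineno, str(exc)) from exc
    if header is None:
        raise FileFormatError(path, None, "empty residency file")
    return records


# ---------------------------------------------------------------- parentage


def write_parentage(records: Iterable[ParentageRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["offspring_id", "mother_id", "sire_id", "birth_date"])
        for r in records:
            w.writerow([r.offspring_id, r.mother_id, r.sire_id or "", _fmt_date(r.birth_date)])


def read_parentage(path) -> list[ParentageRecord]:
    out = []
    with _open_text(path) as fh:
        header = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header != ["offspring_id", "mother_id", "sire_id", "birth_date"]:
                    raise FileFormatError(path, lineno, f"unexpected header {header!r}")
                continue
            if len(fields) != 4:
                raise FileFormatError(path, lineno, f"expected 4 fields, got {len(fields)}")
            off, mother, sire, birth = fields
            out.append(
                ParentageRecord(
                    offspring_id=off,
                    mother_id=mother,
                    sire_id=sire or None,
                    birth_date=_parse_date(birth, path, lineno),
                )
            )
    if header is None:
        raise FileFormatError(path, None, "empty parentage file")
    return out


# ----------------------------------------------------------------- pedigree


def write_pedigree(pedigree: Pedigree, path) -> None:
    with _open_text(path, "wt") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "sire", "dam"])
        for ind, sire, dam in pedigree.to_trios():
            w.writerow([ind, sire or "0", dam or "0"])


def read_pedigree(path) -> Pedigree:
    trios = []
    with _open_text(path) as fh:
        header = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header != ["id", "sire", "dam"]:
                    raise FileFormatError(path, lineno, f"unexpected header {header!r}")
                continue
            if len(fields) != 3:
                raise FileFormatError(path, lineno, f"expected 3 fields, got {len(fields)}")
            ind, sire, dam = fields
            trios.append(
                (ind, None if sire in ("", "0") else sire, None if dam in ("", "0") else dam)
            )
    if header is None:
        raise FileFormatError(path, None, "empty pedigree file")
    return Pedigree.from_trios(trios)


# -------------------------------------------------------- beagle likelihoods


def write_beagle(gl: GenotypeLikelihoodMatrix, path) -> None:
    """Beagle-style GL text file: marker, allele1, allele2, 3 cols/individual."""
    with _open_text(path, "wt") as fh:
        cols = ["marker", "allele1", "allele2"]
        for ind in gl.individuals:
            cols += [ind] * 3
        fh.write("\t".join(cols) + "\n")
        alleles = gl.alleles if gl.alleles is not None else np.tile(["0", "1"], (len(gl.sites), 1))
        for s, site in enumerate(gl.sites):
            fields = [site, str(alleles[s][0]), str(alleles[s][1])]
            for i in range(len(gl.individuals)):
                triple = gl.values[i, s]
                if np.isnan(triple[0]):
                    fields += ["0", "0", "0"]
                else:
                    # full precision so normalized triples survive the round trip
                    fields += [repr(float(v)) for v in triple]
            fh.write("\t".join(fields) + "\n")


def read_beagle(path) -> GenotypeLikelihoodMatrix:
    """Read a beagle GL file; renormalizes off-sum triples with a warning.

    A ``0 0 0`` triple marks a missing site.  Truncated gzip input raises a
    clean :class:`FileFormatError`.
    """
    sites: list[str] = []
    alleles: list[tuple[str, str]] = []
    rows: list[np.ndarray] = []
    individuals: list[str] = []
    renormalized = 0
    try:
        with _open_text(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if not individuals:  # first non-comment line is the header
                    if fields[:3] != ["marker", "allele1", "allele2"]:
                        raise FileFormatError(
                            path, lineno, "header must start with marker/allele1/allele2"
                        )
                    body = fields[3:]
                    if len(body) % 3 != 0:
                        raise FileFormatError(
                            path, lineno, "individual columns not a multiple of 3"
                        )
                    individuals = body[::3]
                    continue
                expected = 3 + 3 * len(individuals)
                if len(fields) != expected:
                    raise FileFormatError(
                        path, lineno, f"expected {expected} fields, got {len(fields)}"
                    )
                sites.append(fields[0])
                alleles.append((fields[1], fields[2]))
                try:
                    vals = np.array([float(x) for x in fields[3:]]).reshape(-1, 3)
                except ValueError:
                    raise FileFormatError(path, lineno, "non-numeric likelihood") from None
                if np.any(vals < 0):
                    raise FileFormatError(path, lineno, "negative likelihood")
                sums = vals.sum(axis=1)
                missing = sums == 0.0
                off = ~missing & (np.abs(sums - 1.0) > 1e-9)
                if off.any():
                    renormalized += int(off.sum())
                    vals[~missing] = vals[~missing] / sums[~missing, None]
                vals[missing] = np.nan
                rows.append(vals)
    except (EOFError, gzip.BadGzipFile) as exc:
        raise FileFormatError(path, None, f"truncated or corrupt gzip input: {exc}") from exc
    if not individuals:
        raise FileFormatError(path, None, "empty beagle file")
    if renormalized:
        warnings.warn(
            f"{path}: renormalized {renormalized} non-normalized likelihood triple(s)",
            stacklevel=2,
        )
    values = np.stack(rows, axis=1) if rows else np.empty((len(individuals), 0, 3))
    return GenotypeLikelihoodMatrix(
        individuals=individuals,
        sites=sites,
        values=values,
        alleles=np.array(alleles) if alleles else None,
    )


# -------------------------------------------------------------- frequencies


def write_frequencies(sites: Sequence[str], freqs: np.ndarray, path) -> None:
    pd.DataFrame({"site": list(sites), "maf": np.asarray(freqs, dtype=float)}).to_csv(
        path, sep="\t", index=False
    )


def read_frequencies(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"site": str, "maf": float})
    except (ValueError, EOFError) as exc:
        raise FileFormatError(path, None, f"cannot parse frequency table: {exc}") from exc
    if list(df.columns) != ["site", "maf"]:
        raise FileFormatError(path, None, f"expected columns site/maf, got {list(df.columns)}")
    if ((df["maf"] <= 0) | (df["maf"] >= 1)).any():
        bad = df.index[(df["maf"] <= 0) | (df["maf"] >= 1)][0]
        raise FileFormatError(path, int(bad) + 2, "minor allele frequency outside (0, 1)")
    return df


# --------------------------------------------------------------- pair table


def write_pair_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_pair_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(PAIR_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FileFormatError(path, None, f"pair table lacks columns {sorted(missing)}")
    return df


# ------------------------------------------------------- relatedness output


def write_relatedness(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_relatedness(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = {"a", "b", "r"}
    if not needed <= set(df.columns):
        raise FileFormatError(path, None, f"relatedness table lacks columns {sorted(needed)}")
    return df


# ----------------------------------------------------------------- reports


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(outdir, seed: int, inputs: dict[str, str], extra: Optional[dict] = None) -> None:
    """Reproducibility manifest: versions, seed, input hashes."""
    import scipy

    from . import __version__

    manifest = {
        "package": {"name": "dyadkin", "version": __version__},
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__, "pandas": pd.__version__},
        "seed": seed,
        "input_sha256": {k: file_sha256(v) for k, v in inputs.items()},
    }
    if extra:
        manifest.update(extra)
    write_json(manifest, Path(outdir) / "manifest.json")
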