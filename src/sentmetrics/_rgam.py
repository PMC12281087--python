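"""Subprocess bridge to the mgcv additive-model engine.

The additive-model fits are delegated to mgcv (the reference implementation
of penalized-spline GAMMs with REML smoothing-parameter selection), driven
through a small R script shipped with the package. Data travel as TSV, model
specifications and results as JSON. Several models can be fitted against the
same table in a single R session, which is how model comparisons guarantee
identical rows.
"""

from __future__ import annotations

import json
import re
import shutil
import subprocess
import tempfile
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

__all__ = ["RGamError", "run_gam_fits", "check_r_available"]

_IDENT_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_.]*$")


class RGamError(RuntimeError):
    """A model fit failed inside the R engine (diagnostics attached)."""


def _r_script_path() -> Path:
    return Path(resources.files("sentmetrics") / "r" / "fit_gamm.R")


def check_r_available() -> None:
    if shutil.which("Rscript") is None:
        raise RGamError("Rscript not found on PATH; the evaluation stage requires R + mgcv")


def validate_identifier(name: str) -> str:
    """Column/term names are injected into R formulas; restrict the charset."""
    if not _IDENT_RE.match(name):
        raise ValueError(f"invalid model-term identifier {name!r}")
    return name


def run_gam_fits(
    table: pd.DataFrame,
    specs: Mapping[str, dict[str, Any]],
    grid_points: int = 100,
    ci_level: float = 0.99,
) -> dict[str, dict[str, Any]]:
    """Fit every spec against ``table`` in one R session.

    Each spec dict needs: ``formula`` (R formula string), ``factors`` (columns
    to coerce to factor), ``smooth_vars`` (numeric smooth predictors whose
    partial effects are exported). Returns the parsed per-model JSON payloads;
    raises :class:`RGamError` if any fit reports an error.
    """
    check_r_available()
    with tempfile.TemporaryDirectory(prefix="sentmetrics_gam_") as tmp:
        tmpdir = Path(tmp)
        data_path = tmpdir / "data.tsv"
        specs_path = tmpdir / "specs.json"
        out_path = tmpdir / "out.json"
        table.to_csv(data_path, sep="\t", index=False)
        payload = {
            name: {**spec, "grid_points": grid_points, "ci_level": ci_level}
            for name, spec in specs.items()
        }
        specs_path.write_text(json.dumps(payload))
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(_r_script_path()), str(data_path), str(specs_path), str(out_path)],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0 or not out_path.exists():
            raise RGamError(
                f"R engine failed (exit {proc.returncode}):\n{proc.stderr.strip()}"
            )
        results = json.loads(out_path.read_text())
    errors = {name: res["error"] for name, res in results.items() if "error" in res}
    if errors:
        msgs = "; ".join(f"{name}: {msg}" for name, msg in errors.items())
        raise RGamError(f"model fit failed: {msgs}")
    return results
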