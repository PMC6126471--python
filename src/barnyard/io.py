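"""Reading count inputs and writing estimate reports.

Counts come in as three CLI integers, a two-column TSV (``key<TAB>value`` with
keys ``n_type1``, ``n_type2``, ``n_mixed``), or a JSON object with the same
keys.  Estimates go out as JSON (machine interface) and TSV (human report);
both carry full-precision values plus 3-decimal display fields.  All writes go
through a write-to-temp-then-rename helper so no partial file survives an
error.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

from .model import DropletCounts, MultipletEstimate, ValidationError

COUNT_KEYS = ("n_type1", "n_type2", "n_mixed")


def read_counts(path: str | Path) -> DropletCounts:
    """Read a DropletCounts from a JSON object or key/value TSV file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json" or text.lstrip().startswith("{"):
        data = json.loads(text)
    else:
        data = {}
        for line in text.splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(f"expected key<TAB>value lines in {path}, got {line!r}")
            data[parts[0].strip()] = float(parts[1])
    missing = [k for k in COUNT_KEYS if k not in data]
    if missing:
        raise ValidationError(f"counts file {path} is missing keys: {', '.join(missing)}")
    return DropletCounts(**{k: float(data[k]) for k in COUNT_KEYS})


def estimate_to_dict(est: MultipletEstimate) -> dict:
    """JSON-ready representation of an estimate (full precision + 3-decimal display)."""
    return {
        "multiplet_frequency": est.multiplet_frequency,
        "multiplet_frequency_display": f"{est.multiplet_frequency:.3f}",
        "mu1": est.load.mu1,
        "mu2": est.load.mu2,
        "n_total_droplets": est.load.n_droplets,
        "n_nonempty": est.counts.n_nonempty,
        "doublet_approximation": est.doublet_approximation,
        "doublet_approximation_display": f"{est.doublet_approximation:.3f}",
        "counts": {
            "n_type1": est.counts.n_type1,
            "n_type2": est.counts.n_type2,
            "n_mixed": est.counts.n_mixed,
        },
    }


def estimate_to_tsv(est: MultipletEstimate) -> str:
    """Human-readable key/value report, one quantity per line."""
    d = estimate_to_dict(est)
    lines = [
        ("n_type1", d["counts"]["n_type1"]),
        ("n_type2", d["counts"]["n_type2"]),
        ("n_mixed", d["counts"]["n_mixed"]),
        ("n_nonempty", d["n_nonempty"]),
        ("n_total_droplets", d["n_total_droplets"]),
        ("mu1", d["mu1"]),
        ("mu2", d["mu2"]),
        ("multiplet_frequency", d["multiplet_frequency"]),
        ("multiplet_frequency_display", d["multiplet_frequency_display"]),
        ("doublet_approximation", d["doublet_approximation"]),
        ("doublet_approximation_display", d["doublet_approximation_display"]),
    ]
    return "".join(f"{k}\t{v}\n" for k, v in lines)


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write ``text`` to ``path`` via a temp file in the same directory + rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
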