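"""Front output: CSV table, console table and a static scatter plot."""

from __future__ import annotations

import logging
from pathlib import Path

from .search import ParetoArchive

logger = logging.getLogger(__name__)

CSV_COLUMNS = [
    "design_id",
    "knockouts",
    "n_kos",
    "growth_rate",
    "product_flux",
    "coupling_strength",
    "coupling_class",
]


def _sorted_rows(archive: ParetoArchive, candidates) -> list[dict]:
    from .refine import expand_design

    rows = []
    for design, fit in archive.entries:
        kos = expand_design(design, candidates)
        rows.append(
            {
                "knockouts": "|".join(kos),
                "n_kos": len(kos),
                "growth_rate": fit.growth,
                "product_flux": fit.product,
                "coupling_strength": fit.coupling,
                "coupling_class": fit.coupling_class,
            }
        )
    rows.sort(
        key=lambda r: (-r["growth_rate"], -r["product_flux"], r["knockouts"])
    )
    for i, row in enumerate(rows, start=1):
        row["design_id"] = f"D{i}"
    return rows


def _fmt(x: float) -> str:
    return format(x, ".6g")


def write_front_csv(archive: ParetoArchive, candidates, path: str | Path) -> None:
    """One row per design, floats at 6 significant digits.

    Rows are sorted by descending growth rate, then descending product
    flux; an empty archive yields a header-only file and a warning.
    """
    rows = _sorted_rows(archive, candidates)
    if not rows:
        logger.warning("empty archive: writing header-only CSV to %s", path)
    lines = [",".join(CSV_COLUMNS)]
    for r in rows:
        lines.append(
            ",".join(
                [
                    r["design_id"],
                    r["knockouts"],
                    str(r["n_kos"]),
                    _fmt(r["growth_rate"]),
                    _fmt(r["product_flux"]),
                    _fmt(r["coupling_strength"]),
                    r["coupling_class"],
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def format_front_table(archive: ParetoArchive, candidates) -> str:
    """Fixed-width console rendering of the front."""
    rows = _sorted_rows(archive, candidates)
    if not rows:
        return "(empty front)"
    header = (
        f"{'id':<5}{'knockouts':<40}{'n':>3}{'growth':>10}"
        f"{'product':>10}{'coupling':>10}  class"
    )
    out = [header, "-" * len(header)]
    for r in rows:
        out.append(
            f"{r['design_id']:<5}{r['knockouts']:<40}{r['n_kos']:>3}"
            f"{_fmt(r['growth_rate']):>10}{_fmt(r['product_flux']):>10}"
            f"{_fmt(r['coupling_strength']):>10}  {r['coupling_class']}"
        )
    return "\n".join(out)


def plot_front(archive: ParetoArchive, path: str | Path) -> bool:
    """Scatter growth vs product, colored by coupling strength.

    Returns False (and warns) without writing when the archive is
    empty.
    """
    if not archive.entries:
        logger.warning("empty archive: no plot written")
        return False
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    growth = [f.growth for _, f in archive.entries]
    product = [f.product for _, f in archive.entries]
    coupling = [f.coupling for _, f in archive.entries]
    fig, ax = plt.subplots(figsize=(6, 4.5))
    sc = ax.scatter(
        growth, product, c=coupling, cmap="viridis", vmin=-1, vmax=1,
        s=60, edgecolor="k", linewidth=0.5,
    )
    fig.colorbar(sc, ax=ax, label="coupling strength")
    ax.set_xlabel("growth rate (1/h)")
    ax.set_ylabel("guaranteed product flux (mmol/gDW/h)")
    ax.set_title("Pareto front of knockout designs")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return True
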