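"""HTML run report: an index page with library totals, the category
pie and length distribution, plus per-subgroup detail pages linking
the genome / TE / transcript analysis folders."""

from __future__ import annotations

import html
from pathlib import Path

from .pipeline import SUBGROUPS, LibraryResult, ReportBundle

_PAGE = """<!doctype html>
<html><head><meta charset="utf-8"><title>{title}</title>
<style>body{{font-family:sans-serif;margin:2em}}table{{border-collapse:collapse}}
td,th{{border:1px solid #999;padding:2px 8px}}</style></head>
<body><h1>{title}</h1>{body}</body></html>
"""


def _check_exists(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"report references missing file: {path}")
    return path


def _link(base: Path, target: Path) -> str:
    rel = target.relative_to(base)
    return f'<a href="{rel}">{html.escape(str(rel))}</a>'


def _library_page(lib: LibraryResult) -> None:
    base = lib.outdir
    rows = [
        ("input reads", lib.n_input),
        ("length-selected reads", lib.n_filtered),
        ("genome mappers", lib.n_genome_mappers),
        ("genome-unique mappers", lib.n_genome_unique),
    ]
    totals = "".join(f"<tr><th>{k}</th><td>{v}</td></tr>" for k, v in rows)
    pie = "".join(
        f"<tr><th>{html.escape(c)}</th><td>{p:.2f}%</td></tr>"
        for c, p in lib.pie.items()
    )
    sizes = "".join(
        f"<tr><th>{k}</th><td>{v}</td></tr>" for k, v in lib.subgroups.sizes().items()
    )
    sections = [
        f"<h2>Totals</h2><table>{totals}</table>",
        f"<h2>Genome-mapper categories</h2><table>{pie}</table>",
        f"<h2>Subgroups</h2><table>{sizes}</table>",
    ]
    for sub in SUBGROUPS:
        links = []
        for folder in ("genome", "TE", "transcripts"):
            d = base / sub / folder
            if d.is_dir():
                for f in sorted(d.iterdir()):
                    links.append(f"<li>{_link(base, _check_exists(f))}</li>")
        sections.append(f"<h2>{sub} — view details</h2><ul>{''.join(links)}</ul>")
    pp_links = "".join(
        f"<li>{_link(base, _check_exists(f))}</li>"
        for f in sorted((base / 'pingpong').iterdir())
    )
    sections.append(f"<h2>ping-pong signature</h2><ul>{pp_links}</ul>")
    for extra in ("pie.tsv", "length_distribution.tsv"):
        p = base / extra
        if p.exists():
            sections.append(f"<p>{_link(base, p)}</p>")
    (base / "index.html").write_text(
        _PAGE.format(title=f"library {html.escape(lib.name)}", body="".join(sections))
    )


def render_index_from_summary(outdir: str | Path) -> Path:
    """Rebuild the top-level index.html of a finished run from summary.json."""
    import json

    outdir = Path(outdir)
    summary = json.loads(_check_exists(outdir / "summary.json").read_text())
    items = []
    for name, lib in summary["libraries"].items():
        page = outdir / name / "index.html"
        link = (
            f'<a href="{page.relative_to(outdir)}">{html.escape(name)}</a>'
            if page.exists()
            else html.escape(name)
        )
        items.append(
            f"<li>{link} — {lib['genome_mappers']} genome mappers, "
            f"{lib['genome_unique']} genome-unique</li>"
        )
    body = (
        f"<ul>{''.join(items)}</ul>"
        '<p>provenance: <a href="summary.json">summary.json</a></p>'
    )
    index = outdir / "index.html"
    index.write_text(_PAGE.format(title="small RNA analysis report", body=body))
    return index


def render_report(bundle: ReportBundle) -> Path:
    """Write index.html for the run and one page per library.

    Every referenced file is checked to exist; a missing file raises
    ``FileNotFoundError`` naming the path.
    """
    outdir = Path(bundle.config.outdir)
    items = []
    for lib in bundle.libraries:
        _library_page(lib)
        page = _check_exists(lib.outdir / "index.html")
        rel = page.relative_to(outdir)
        items.append(
            f"<li><a href=\"{rel}\">{html.escape(lib.name)}</a> — "
            f"{lib.n_genome_mappers} genome mappers, "
            f"{lib.n_genome_unique} genome-unique</li>"
        )
    body = f"<ul>{''.join(items)}</ul><p>provenance: <a href=\"summary.json\">summary.json</a></p>"
    index = outdir / "index.html"
    index.write_text(_PAGE.format(title="small RNA analysis report", body=body))
    _check_exists(outdir / "summary.json")
    return index
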