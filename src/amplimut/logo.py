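"""Mutation logo: reference row, consensus row, and frequency-ranked
alternative outcomes per position.

The logo reads bottom-to-top: the reference sequence (protospacer window
highlighted), the consensus of all retained sequences (non-reference bases
offset), then up to ``max_alt`` rows of alternative outcomes ranked by
decreasing frequency.  Substituted or inserted bases are drawn as A/C/G/T in
purple, deletions as 'D' in green; letter opacity is proportional to
frequency, normalized per column so low-efficiency runs stay legible.  An
arrow marks the canonical cleavage site.  Rendering is a pure function of
the model: the same model always yields byte-identical SVG.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

from .calls import BASES, PositionTally
from .model import AmpliconSpec, GuideTarget


@dataclass
class LogoGlyph:
    glyph: str        # A/C/G/T or D
    cls: str          # mismatch | insertion | deletion
    frequency: float


@dataclass
class LogoColumn:
    position: int               # reference index
    ref_base: str
    consensus_base: str         # A/C/G/T or D
    alternatives: list[LogoGlyph] = field(default_factory=list)


@dataclass
class LogoModel:
    name: str
    columns: list[LogoColumn]
    cut_sites: list[int]        # between-base ref coordinates
    windows: list[tuple[int, int]]  # protospacer spans, half-open


def build_logo(tally: PositionTally, spec: AmpliconSpec,
               max_alt: int = 4) -> LogoModel:
    """Build the logo model from a per-position tally.

    The consensus is the modal observed state per column (reference wins
    ties); alternatives are all non-reference outcomes with nonzero
    frequency, ranked by decreasing frequency and capped at ``max_alt``.
    """
    denom = max(tally.total_adjusted, 1)
    columns = []
    for i, p in enumerate(tally.positions):
        ref_base = tally.spec.ref_seq[p]
        del_n = int(tally.deletion[i, 0])
        mm = tally.mismatch[i, :, 0]
        ins_total = int(tally.insertion[i, 0])
        ins_b = tally.ins_base[i, :, 0]
        ref_n = denom - del_n - int(mm.sum())
        # modal observed state at this column (insertions live between
        # columns and do not compete for the consensus)
        states = {b: int(mm[j]) for j, b in enumerate(BASES) if b != ref_base}
        states["D"] = del_n
        best_alt = max(states, key=lambda b: (states[b], b))
        consensus = ref_base if ref_n >= states[best_alt] else best_alt
        alts = []
        for j, b in enumerate(BASES):
            if b != ref_base and mm[j] > 0:
                alts.append(LogoGlyph(b, "mismatch", mm[j] / denom))
            if ins_b[j] > 0:
                alts.append(LogoGlyph(b, "insertion", ins_b[j] / denom))
        if del_n > 0:
            alts.append(LogoGlyph("D", "deletion", del_n / denom))
        alts.sort(key=lambda g: (-g.frequency, g.glyph, g.cls))
        columns.append(LogoColumn(position=int(p), ref_base=ref_base,
                                  consensus_base=consensus,
                                  alternatives=alts[:max_alt]))
    return LogoModel(name=spec.name, columns=columns,
                     cut_sites=[t.cut_site for t in spec.targets],
                     windows=[(t.proto_start, t.proto_start + 20)
                              for t in spec.targets])


_COL_W = 14.0
_ROW_H = 18.0
_MARGIN = 24.0
_COLORS = {"mismatch": "#7d2fa0", "insertion": "#7d2fa0",
           "deletion": "#1d8a3c", "ref": "#444444", "ref_window": "#c0282d",
           "consensus": "#2456b0"}
_MIN_OPACITY = 0.05


def _fmt(x: float) -> str:
    return f"{x:.2f}".rstrip("0").rstrip(".")


def render_svg(model: LogoModel, path: str,
               colors: dict[str, str] = _COLORS) -> None:
    """Write the logo as a deterministic standalone SVG file."""
    cols = model.columns
    n_alt_rows = max((len(c.alternatives) for c in cols), default=0)
    width = _MARGIN * 2 + _COL_W * len(cols)
    height = _MARGIN * 2 + _ROW_H * (n_alt_rows + 2)
    pos_to_col = {c.position: i for i, c in enumerate(cols)}

    def x_of(col: int) -> float:
        return _MARGIN + _COL_W * (col + 0.5)

    def y_of(row: int) -> float:
        # row 0 = reference (bottom), 1 = consensus, 2.. = alternatives
        return height - _MARGIN - _ROW_H * row - 4.0

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_fmt(width)}" '
        f'height="{_fmt(height)}" viewBox="0 0 {_fmt(width)} {_fmt(height)}">',
        f'<title>{model.name}</title>',
    ]
    # protospacer-window highlights behind the reference row
    window_cols = set()
    for lo, hi in model.windows:
        for p in range(lo, hi):
            if p in pos_to_col:
                window_cols.add(pos_to_col[p])
    for i in sorted(window_cols):
        parts.append(
            f'<rect x="{_fmt(_MARGIN + _COL_W * i)}" '
            f'y="{_fmt(y_of(0) - _ROW_H + 4.0)}" width="{_fmt(_COL_W)}" '
            f'height="{_fmt(_ROW_H)}" fill="#f6e3e3"/>')
    # cleavage-site arrows
    for cut in model.cut_sites:
        if cut in pos_to_col:
            xa = _MARGIN + _COL_W * pos_to_col[cut]
            ya = y_of(0) - _ROW_H
            parts.append(
                f'<path d="M {_fmt(xa)} {_fmt(ya - 10)} L {_fmt(xa - 4)} '
                f'{_fmt(ya - 18)} L {_fmt(xa + 4)} {_fmt(ya - 18)} Z" '
                f'fill="#000000"/>')
    glyph_fmt = ('<text x="{x}" y="{y}" font-family="monospace" '
                 'font-size="14" text-anchor="middle" fill="{fill}"'
                 '{extra}>{g}</text>')
    max_col_freq = [max((g.frequency for g in c.alternatives), default=0.0)
                    for c in cols]
    for i, c in enumerate(cols):
        in_window = i in window_cols
        fill = colors["ref_window"] if in_window else colors["ref"]
        parts.append(glyph_fmt.format(x=_fmt(x_of(i)), y=_fmt(y_of(0)),
                                      fill=fill, extra="", g=c.ref_base))
        # consensus row; non-reference consensus is offset and recolored
        if c.consensus_base == c.ref_base:
            parts.append(glyph_fmt.format(x=_fmt(x_of(i)), y=_fmt(y_of(1)),
                                          fill=colors["ref"], extra="",
                                          g=c.consensus_base))
        else:
            parts.append(glyph_fmt.format(x=_fmt(x_of(i)),
                                          y=_fmt(y_of(1) - 4.0),
                                          fill=colors["consensus"], extra="",
                                          g=c.consensus_base))
        for r, glyph in enumerate(c.alternatives):
            opacity = max(_MIN_OPACITY,
                          glyph.frequency / max_col_freq[i]
                          if max_col_freq[i] else 0.0)
            fill = (colors["deletion"] if glyph.cls == "deletion"
                    else colors[glyph.cls])
            extra = f' opacity="{_fmt(opacity)}"'
            parts.append(glyph_fmt.format(x=_fmt(x_of(i)), y=_fmt(y_of(2 + r)),
                                          fill=fill, extra=extra,
                                          g=glyph.glyph))
    parts.append("</svg>")
    with open(path, "w") as fh:
        fh.write("\n".join(parts) + "\n")


def logo_json(model: LogoModel, path: str) -> None:
    """Machine-readable mirror of the logo model."""
    with open(path, "w") as fh:
        json.dump(asdict(model), fh, indent=1, sort_keys=True)
        fh.write("\n")
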