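"""Minimal CIF 1.1 reader/writer.

Covers the subset of CIF used by monomer-dictionary files and by mmCIF
coordinate files: data blocks, single ``_tag value`` items, ``loop_``
tables, quoted strings and semicolon text fields.  Values ``.`` and ``?``
are mapped to ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class CifSyntaxError(ValueError):
    pass


@dataclass
class Loop:
    tags: list[str]
    rows: list[list[str | None]]


@dataclass
class Block:
    name: str
    items: dict[str, str | None] = field(default_factory=dict)
    loops: list[Loop] = field(default_factory=list)


def _tokenize(text: str):
    """Yield (kind, value) with kind in {'data', 'loop', 'tag', 'value'}."""
    lines = text.splitlines()
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i]
        if line.startswith(";"):
            # semicolon text field: runs to the next line that is just ';'
            buf = [line[1:]]
            i += 1
            while i < n and not lines[i].startswith(";"):
                buf.append(lines[i])
                i += 1
            if i >= n:
                raise CifSyntaxError("unterminated semicolon text field")
            i += 1
            yield ("value", "\n".join(buf))
            continue
        j = 0
        ln = len(line)
        while j < ln:
            c = line[j]
            if c in " \t":
                j += 1
                continue
            if c == "#":
                break
            if c in "'\"":
                quote = c
                k = j + 1
                while True:
                    k = line.find(quote, k)
                    if k == -1:
                        raise CifSyntaxError(f"unterminated quote: {line!r}")
                    if k + 1 >= ln or line[k + 1] in " \t":
                        break
                    k += 1
                yield ("value", line[j + 1 : k])
                j = k + 1
                continue
            # bare token
            k = j
            while k < ln and line[k] not in " \t":
                k += 1
            tok = line[j:k]
            j = k
            low = tok.lower()
            if low.startswith("data_"):
                yield ("data", tok[5:])
            elif low == "loop_":
                yield ("loop", None)
            elif tok.startswith("_"):
                yield ("tag", tok)
            elif low in ("stop_", "global_") or low.startswith("save_"):
                raise CifSyntaxError(f"unsupported CIF construct: {tok}")
            else:
                yield ("value", tok)
        i += 1


def _plain(v: str | None) -> str | None:
    if v in (".", "?"):
        return None
    return v


def parse(text: str) -> list[Block]:
    blocks: list[Block] = []
    block: Block | None = None
    toks = list(_tokenize(text))
    i = 0
    n = len(toks)
    while i < n:
        kind, val = toks[i]
        if kind == "data":
            block = Block(name=val)
            blocks.append(block)
            i += 1
        elif kind == "loop":
            if block is None:
                raise CifSyntaxError("loop_ outside a data block")
            i += 1
            tags: list[str] = []
            while i < n and toks[i][0] == "tag":
                tags.append(toks[i][1])
                i += 1
            if not tags:
                raise CifSyntaxError("loop_ without tags")
            values: list[str | None] = []
            while i < n and toks[i][0] == "value":
                values.append(_plain(toks[i][1]))
                i += 1
            if not values and i < n:
                # empty loop bodies are tolerated (header-only tables)
                pass
            if len(values) % len(tags) != 0:
                raise CifSyntaxError(
                    f"loop row length mismatch for tags {tags}: {len(values)} values"
                )
            rows = [values[k : k + len(tags)] for k in range(0, len(values), len(tags))]
            block.loops.append(Loop(tags=tags, rows=rows))
        elif kind == "tag":
            if block is None:
                raise CifSyntaxError("item outside a data block")
            if i + 1 >= n or toks[i + 1][0] != "value":
                raise CifSyntaxError(f"tag {val} without a value")
            block.items[val] = _plain(toks[i + 1][1])
            i += 2
        else:
            raise CifSyntaxError(f"unexpected value token {val!r}")
    return blocks


def category_rows(blocks: list[Block], category: str) -> list[dict[str, str | None]]:
    """All rows of a category across blocks; single items form one row per block.

    ``category`` is given without the trailing dot, e.g. ``_chem_comp_atom``.
    Keys in the returned dicts are the tag parts after the dot.
    """
    prefix = category + "."
    rows: list[dict[str, str | None]] = []
    for block in blocks:
        single = {
            t[len(prefix) :]: v for t, v in block.items.items() if t.startswith(prefix)
        }
        if single:
            rows.append(single)
        for loop in block.loops:
            if loop.tags[0].startswith(prefix):
                names = [t[len(prefix) :] for t in loop.tags]
                for r in loop.rows:
                    rows.append(dict(zip(names, r)))
    return rows


def categories_present(blocks: list[Block]) -> set[str]:
    cats: set[str] = set()
    for block in blocks:
        for t in block.items:
            cats.add(t.split(".")[0])
        for loop in block.loops:
            cats.add(loop.tags[0].split(".")[0])
    return cats


# --- writing -----------------------------------------------------------------

_SPECIAL_START = "_#$'\"[]"


def format_value(v) -> str:
    if v is None:
        return "."
    s = str(v)
    if s == "":
        return "''"
    if any(c in s for c in " \t") or s[0] in _SPECIAL_START or s.lower() in (
        "loop_",
        "stop_",
        "global_",
    ) or s.lower().startswith("data_"):
        if "'" not in s:
            return f"'{s}'"
        if '"' not in s:
            return f'"{s}"'
        raise CifSyntaxError(f"cannot quote value {s!r}")
    return s


def write_loop(out: list[str], tags: list[str], rows: list[list]) -> None:
    if not rows:
        return
    out.append("loop_")
    out.extend(tags)
    cells = [[format_value(v) for v in row] for row in rows]
    widths = [max(len(r[i]) for r in cells) for i in range(len(tags))]
    for r in cells:
        out.append(" ".join(c.ljust(w) for c, w in zip(r, widths)).rstrip())
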