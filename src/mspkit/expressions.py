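"""Safe map-calculator mini-language for layer pre-processing.

Case-study configurations derive model-ready layers from raw layers through
small arithmetic expressions such as ``norm(log1p(shipping + ports))`` or
``where(depth < 50, trawling, 0)``.  Expressions are parsed into a closed
syntax tree (identifiers, numbers, + - * /, comparisons, a fixed function
whitelist) and evaluated by a tree-walking interpreter — user text is never
handed to the host language.

Grammar notes
-------------
Identifiers are layer codes matching ``[A-Za-z_][A-Za-z0-9_-]*`` with
maximal munch, so ``a-b`` lexes as ONE identifier; write ``a - b`` (with
spaces) for subtraction.  Comparisons accept both ``=``/``==`` and
``!=``/``<>`` and yield 0/1 mask layers so they compose with arithmetic.
Nodata (NaN) propagates through every operator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from . import grid as ge
from .grid import GridLayer, GridError

__all__ = ["Expression", "ExpressionError", "parse_expression", "evaluate_expression"]

#: Whitelisted functions: name -> (min arity, max arity or None for varargs)
FUNCTIONS = {
    "norm": (1, 1),
    "log1p": (1, 1),
    "gaussian": (2, 2),
    "rescale": (3, 3),
    "where": (3, 3),
    "min": (1, None),
    "max": (1, None),
    "sum": (1, None),
    "mean": (1, None),
}


class ExpressionError(ValueError):
    """Parse or evaluation failure, annotated with the source offset."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (at offset {offset})"
        super().__init__(message)
        self.offset = offset


_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<num>(\d+\.\d*|\.\d+|\d+)([eE][+-]?\d+)?)
  | (?P<ident>[A-Za-z_][A-Za-z0-9_-]*)
  | (?P<op><=|>=|==|!=|<>|[+\-*/<>=(),])
    """,
    re.VERBOSE,
)


def _tokenize(text: str):
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise ExpressionError(f"unexpected character {text[pos]!r}", pos)
        if m.lastgroup != "ws":
            kind = m.lastgroup
            val = m.group()
            if kind == "op" and val in ("==", "="):
                val = "=="
            if kind == "op" and val == "<>":
                val = "!="
            tokens.append((kind, val, pos))
        pos = m.end()
    tokens.append(("end", "", len(text)))
    return tokens


# AST nodes are plain tuples:
#   ("num", value) | ("ident", name) | ("neg", operand)
#   ("bin", op, left, right) | ("cmp", op, left, right)
#   ("call", fname, [args...])


class _Parser:
    """Recursive descent: comparison < additive < multiplicative < unary < primary."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i]

    def next(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, value: str):
        kind, val, pos = self.next()
        if val != value:
            raise ExpressionError(f"expected {value!r}, found {val or 'end of input'!r}", pos)

    def parse(self):
        tree = self.comparison()
        kind, val, pos = self.peek()
        if kind != "end":
            raise ExpressionError(f"unexpected trailing input {val!r}", pos)
        return tree

    def comparison(self):
        left = self.additive()
        kind, val, pos = self.peek()
        if kind == "op" and val in ("<", "<=", ">", ">=", "==", "!="):
            self.next()
            right = self.additive()
            return ("cmp", val, left, right)
        return left

    def additive(self):
        node = self.multiplicative()
        while True:
            kind, val, _ = self.peek()
            if kind == "op" and val in ("+", "-"):
                self.next()
                node = ("bin", val, node, self.multiplicative())
            else:
                return node

    def multiplicative(self):
        node = self.unary()
        while True:
            kind, val, _ = self.peek()
            if kind == "op" and val in ("*", "/"):
                self.next()
                node = ("bin", val, node, self.unary())
            else:
                return node

    def unary(self):
        kind, val, _ = self.peek()
        if kind == "op" and val == "-":
            self.next()
            return ("neg", self.unary())
        if kind == "op" and val == "+":
            self.next()
            return self.unary()
        return self.primary()

    def primary(self):
        kind, val, pos = self.next()
        if kind == "num":
            return ("num", float(val))
        if kind == "ident":
            k2, v2, _ = self.peek()
            if k2 == "op" and v2 == "(":
                if val not in FUNCTIONS:
                    raise ExpressionError(
                        f"function {val!r} is not in the whitelist "
                        f"{sorted(FUNCTIONS)}", pos,
                    )
                self.next()
                args = [self.comparison()]
                while self.peek()[1] == ",":
                    self.next()
                    args.append(self.comparison())
                self.expect(")")
                lo, hi = FUNCTIONS[val]
                if len(args) < lo or (hi is not None and len(args) > hi):
                    raise ExpressionError(
                        f"{val}() takes {lo}"
                        + ("" if hi == lo else f"..{hi if hi is not None else 'n'}")
                        + f" arguments, got {len(args)}", pos,
                    )
                return ("call", val, args)
            return ("ident", val)
        if kind == "op" and val == "(":
            node = self.comparison()
            self.expect(")")
            return node
        raise ExpressionError(f"unexpected {val or 'end of input'!r}", pos)


@dataclass(frozen=True)
class Expression:
    """A parsed, purely functional map-calculator expression."""

    source_text: str
    tree: tuple

    def identifiers(self) -> set[str]:
        """Layer names the expression references."""
        out: set[str] = set()

        def walk(node):
            if node[0] == "ident":
                out.add(node[1])
            elif node[0] in ("bin", "cmp"):
                walk(node[2]); walk(node[3])
            elif node[0] == "neg":
                walk(node[1])
            elif node[0] == "call":
                for a in node[2]:
                    walk(a)

        walk(self.tree)
        return out

    def unparse(self) -> str:
        """Canonical, fully parenthesized text; reparses to the same tree."""
        return _unparse(self.tree)


def _unparse(node) -> str:
    t = node[0]
    if t == "num":
        v = node[1]
        return repr(int(v)) if v == int(v) else repr(v)
    if t == "ident":
        return node[1]
    if t == "neg":
        return f"(-{_unparse(node[1])})"
    if t in ("bin", "cmp"):
        return f"({_unparse(node[2])} {node[1]} {_unparse(node[3])})"
    if t == "call":
        return f"{node[1]}({', '.join(_unparse(a) for a in node[2])})"
    raise AssertionError(node)


def parse_expression(text: str) -> Expression:
    """Parse ``text`` into an :class:`Expression` or fail with a positioned error."""
    if not text or not text.strip():
        raise ExpressionError("empty expression")
    tree = _Parser(text).parse()
    return Expression(source_text=text, tree=tree)


def evaluate_expression(expr: Expression, registry: dict) -> GridLayer:
    """Evaluate an expression cellwise over a registry of aligned layers.

    Returns a :class:`GridLayer` on the common grid.  Nodata propagates
    through arithmetic and comparisons; division by zero yields nodata.
    """
    if isinstance(expr, str):
        expr = parse_expression(expr)
    grid = None
    for name in expr.identifiers():
        if name not in registry:
            raise ExpressionError(f"unresolved layer identifier {name!r}")
        layer = registry[name]
        if grid is None:
            grid = layer.grid
        elif not layer.grid.is_aligned(grid):
            raise GridError(f"layer {name!r} is not aligned to the other layers")
    if grid is None and registry:
        grid = next(iter(registry.values())).grid
    result = _eval(expr.tree, registry, grid)
    if not isinstance(result, GridLayer):
        if grid is None:
            raise ExpressionError(
                "expression references no layers; cannot infer the grid"
            )
        result = GridLayer("expr", np.full(grid.shape, float(result)), grid)
    return result.copy(name=expr.source_text.strip())


def _values(x, grid):
    if isinstance(x, GridLayer):
        return x.values
    return np.full(grid.shape, float(x))


def _as_layer(values, grid) -> GridLayer:
    return GridLayer("expr", values, grid)


def _eval(node, registry, grid):
    t = node[0]
    if t == "num":
        return node[1]
    if t == "ident":
        return registry[node[1]]
    if t == "neg":
        v = _eval(node[1], registry, grid)
        return -v if not isinstance(v, GridLayer) else _as_layer(-v.values, grid)
    if t == "bin":
        lv = _eval(node[2], registry, grid)
        rv = _eval(node[3], registry, grid)
        if not isinstance(lv, GridLayer) and not isinstance(rv, GridLayer):
            return _scalar_bin(node[1], lv, rv)
        a, b = _values(lv, grid), _values(rv, grid)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = _scalar_bin(node[1], a, b)
        out = np.where(np.isinf(out), np.nan, out)
        return _as_layer(out, grid)
    if t == "cmp":
        lv = _eval(node[2], registry, grid)
        rv = _eval(node[3], registry, grid)
        a, b = _values(lv, grid), _values(rv, grid)
        nodata = np.isnan(a) | np.isnan(b)
        with np.errstate(invalid="ignore"):
            res = _scalar_cmp(node[1], a, b).astype(np.float64)
        res[nodata] = np.nan
        return _as_layer(res, grid)
    if t == "call":
        return _eval_call(node[1], node[2], registry, grid)
    raise AssertionError(node)


def _scalar_bin(op, a, b):
    if op == "+":
        return a + b
    if op == "-":
        return a - b
    if op == "*":
        return a * b
    return a / b


def _scalar_cmp(op, a, b):
    return {
        "<": np.less, "<=": np.less_equal,
        ">": np.greater, ">=": np.greater_equal,
        "==": np.equal, "!=": np.not_equal,
    }[op](a, b)


def _layer_arg(node, registry, grid) -> GridLayer:
    v = _eval(node, registry, grid)
    if not isinstance(v, GridLayer):
        v = _as_layer(np.full(grid.shape, float(v)), grid)
    return v


def _scalar_arg(node, registry, grid, fname: str) -> float:
    v = _eval(node, registry, grid)
    if isinstance(v, GridLayer):
        raise ExpressionError(f"{fname}() expects a numeric argument, got a layer")
    return float(v)


def _eval_call(fname, args, registry, grid):
    if fname == "norm":
        return ge.normalize(_layer_arg(args[0], registry, grid))
    if fname == "log1p":
        return ge.log_scale(_layer_arg(args[0], registry, grid))
    if fname == "gaussian":
        layer = _layer_arg(args[0], registry, grid)
        dist = _scalar_arg(args[1], registry, grid, "gaussian")
        return ge.gaussian_convolve(layer, dist)
    if fname == "rescale":
        layer = _layer_arg(args[0], registry, grid)
        lo = _scalar_arg(args[1], registry, grid, "rescale")
        hi = _scalar_arg(args[2], registry, grid, "rescale")
        vmin, vmax = np.nanmin(layer.values), np.nanmax(layer.values)
        if vmax == vmin:
            out = np.full(grid.shape, lo, dtype=np.float64)
            out[layer.nodata_mask] = np.nan
        else:
            out = (layer.values - vmin) / (vmax - vmin) * (hi - lo) + lo
        return _as_layer(out, grid)
    if fname == "where":
        cond = _layer_arg(args[0], registry, grid)
        a = _values(_eval(args[1], registry, grid), grid)
        b = _values(_eval(args[2], registry, grid), grid)
        out = np.where(cond.filled(0.0) > 0, a, b)
        out[cond.nodata_mask] = np.nan
        return _as_layer(out, grid)
    # cellwise aggregations over the argument layers (nodata counts as absent)
    stack = np.stack([_layer_arg(a, registry, grid).values for a in args])
    with np.errstate(invalid="ignore"):
        if fname == "min":
            out = np.nanmin(stack, axis=0)
        elif fname == "max":
            out = np.nanmax(stack, axis=0)
        elif fname == "sum":
            out = np.nansum(stack, axis=0)
            out[np.isnan(stack).all(axis=0)] = np.nan
        elif fname == "mean":
            out = np.nanmean(stack, axis=0)
        else:
            raise AssertionError(fname)
    return _as_layer(out, grid)
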