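"""Parametric L-systems for two tomato varieties.

A parametric L-system G = (V, omega, P, Theta) rewrites a string of
parameterized symbols in parallel.  The alphabet couples organ symbols
(L leaf-on-branch, l terminal leaf, F main-stem internode, S short lateral
branch, G fruit, P flower stalk, H flower, Y bud stalk atop the main stem,
y bud, h flowering branch, f non-flowering branch) with rotation operators
(/ & # + -), brackets for branching, and control characters A/B/C/D that
never become geometry but steer which organ symbols appear.

Every organ carries an integer ``age`` that increases by one per growth
stage until the organ matures, after which it takes the stable state ``r``
-- except leaves, for which age r triggers bifurcation into two leaves at
the next rewrite.

The branching plan of a plant is fixed before growth by a *choice string*:
an ordered list of lateral-branch form codes, one of
1 short branch / compound leaf, 2 full branch without flowers, 3 branch
with flowers, 4 terminal branch with leaves only, 5 terminal branch with
flowers; 4/5 may appear once, in last position only.  The main-stem control
A(i, j) consumes one code per stage (i indexes the choice string, j counts
internodes produced), so later codes sprout higher on the stem.

A production ``pred(params) : cond -> succ`` holds for a symbol iff the
letters match, the arities match, and the condition (built from &&, ||,
==, != over the formal parameters) evaluates true.  Grammars are plain
text files, one rule per line; the two defaults (ordinary, cherry) differ
in that the cherry variety puts leaves and flowers on the same branch.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import GrammarError, InvalidChoiceError, StructureError

#: stable-state marker for the age parameter
R = "r"

ORGAN_LETTERS = set("LlFSGPHYyhf")
CONTROL_LETTERS = set("ABCD")
OPERATOR_LETTERS = set("/&#+-")
BRACKETS = set("[]")

ARITY = {"L": 1, "l": 1, "F": 1, "S": 1, "G": 1, "P": 1, "H": 1,
         "Y": 2, "y": 1, "h": 1, "f": 1,
         "A": 2, "B": 2, "C": 1, "D": 2}

#: age at which an organ letter freezes to r (leaves then bifurcate)
DEFAULT_MATURITY = {"F": 5, "S": 5, "f": 5, "h": 5,
                    "L": 4, "l": 4, "G": 6, "H": 3, "P": 3,
                    "Y": 4, "y": 3}

BRANCH_FORMS = (1, 2, 3, 4, 5)
TERMINAL_FORMS = (4, 5)
#: letters whose presence identifies a lateral branch's form
_BRANCH_CODE = {"S": 1, "C": 1, "f": 2, "h": 3}


@dataclass(frozen=True)
class SymbolInstance:
    letter: str
    params: tuple = ()

    def __str__(self) -> str:
        if not self.params:
            return self.letter
        inner = ",".join(str(p) for p in self.params)
        return f"{self.letter}({inner})"


@dataclass
class ChoiceString:
    """Ordered lateral-branch form codes, consumed bottom-to-top."""

    codes: tuple

    def __post_init__(self) -> None:
        self.codes = tuple(int(c) for c in self.codes)
        if not self.codes:
            raise InvalidChoiceError("choice string must be non-empty")
        for c in self.codes:
            if c not in BRANCH_FORMS:
                raise InvalidChoiceError(f"branch form {c} outside {BRANCH_FORMS}")
        for c in self.codes[:-1]:
            if c in TERMINAL_FORMS:
                raise InvalidChoiceError(
                    "terminal forms 4/5 may only appear in last position")

    def __call__(self, i) -> int:
        """Code at index i, or -1 once the string is exhausted."""
        i = int(i)
        return self.codes[i] if 0 <= i < len(self.codes) else -1

    def __len__(self) -> int:
        return len(self.codes)


def random_choice(seed: int, n_branches: tuple[int, int] = (6, 10),
                  p_terminal: float = 0.7) -> ChoiceString:
    """Seeded random branching plan: 1/2/3 codes, optional 4/5 terminal."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_branches[0], n_branches[1] + 1))
    codes = list(rng.choice([1, 2, 3], size=n))
    if rng.random() < p_terminal:
        codes.append(int(rng.choice(TERMINAL_FORMS)))
    return ChoiceString(tuple(codes))


class LString:
    """An ordered, bracket-balanced list of symbol instances."""

    def __init__(self, symbols, choice: ChoiceString | None = None):
        self.symbols = list(symbols)
        self.choice = choice
        self._validate()

    def _validate(self) -> None:
        depth = 0
        for s in self.symbols:
            if s.letter == "[":
                depth += 1
            elif s.letter == "]":
                depth -= 1
                if depth < 0:
                    raise StructureError("unbalanced ']' in L-string")
            elif s.letter in ARITY and len(s.params) != ARITY[s.letter]:
                raise StructureError(
                    f"symbol {s.letter} expects {ARITY[s.letter]} params, "
                    f"got {len(s.params)}")
        if depth != 0:
            raise StructureError("unbalanced '[' in L-string")

    def __iter__(self):
        return iter(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def __eq__(self, other) -> bool:
        return isinstance(other, LString) and str(self) == str(other)

    def __str__(self) -> str:
        return "".join(str(s) for s in self.symbols)

    __repr__ = __str__


_TOKEN = re.compile(r"\s*(?:([A-Za-z])(\(([^()]*)\))?"
                    r"|([\[\]/&#+\-−])(\(([^()]*)\))?)")


def _parse_value(tok: str):
    tok = tok.strip()
    if tok == R:
        return R
    try:
        return int(tok)
    except ValueError:
        return float(tok)


def parse_lstring(text: str, choice: ChoiceString | None = None) -> LString:
    """Parse bracketed text like ``[+L(3)][-L(0)]`` (U+2212 accepted as '-')."""
    symbols = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or not m.group(0).strip():
            if text[pos:].strip() == "":
                break
            raise StructureError(f"cannot parse L-string at: {text[pos:]!r}")
        pos = m.end()
        if m.group(1):
            letter, args = m.group(1), m.group(3)
        else:
            letter = m.group(4).replace("−", "-")
            args = m.group(6)
        params = tuple(_parse_value(t) for t in args.split(",")) if args else ()
        symbols.append(SymbolInstance(letter, params))
    return LString(symbols, choice=choice)


# ---------------------------------------------------------------------------
# productions

_SAFE_NAME = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def _compile_expr(src: str, allowed: set[str], where: str):
    src_py = src.replace("&&", " and ").replace("||", " or ")
    src_py = src_py.replace("−", "-")
    try:
        code = compile(src_py, "<grammar>", "eval")
    except SyntaxError as e:
        raise GrammarError(f"bad expression {src!r} in {where}: {e}") from None
    for name in code.co_names:
        if name not in allowed:
            raise GrammarError(f"unbound name {name!r} in {where} ({src!r})")
    return code


@dataclass
class Production:
    letter: str
    formals: tuple[str, ...]
    cond_src: str
    cond: object = field(repr=False)
    succ: list = field(repr=False)   # list of (letter, [param code objects])
    raw: str = ""

    def matches(self, sym: SymbolInstance, choice) -> bool:
        if sym.letter != self.letter or len(sym.params) != len(self.formals):
            return False
        env = dict(zip(self.formals, sym.params))
        env["r"] = R
        env["choice"] = choice if choice is not None else (lambda i: -1)
        return bool(eval(self.cond, {"__builtins__": {}}, env))

    def expand(self, sym: SymbolInstance, choice) -> list[SymbolInstance]:
        env = dict(zip(self.formals, sym.params))
        env["r"] = R
        env["choice"] = choice if choice is not None else (lambda i: -1)
        out = []
        for letter, param_codes in self.succ:
            params = tuple(eval(c, {"__builtins__": {}}, env)
                           for c in param_codes)
            out.append(SymbolInstance(letter, params))
        return out


_SUCC_TOKEN = re.compile(r"\s*(?:([A-Za-z])(\(([^()]*(?:\([^()]*\)[^()]*)*)\))?"
                         r"|([\[\]/&#+\-−])(\(([^()]*)\))?)")


def _split_args(argstr: str) -> list[str]:
    """Split on commas at paren depth 0 (arguments may call choice(i))."""
    parts, depth, cur = [], 0, []
    for ch in argstr:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "," and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    if cur:
        parts.append("".join(cur))
    return parts


def parse_production(line: str) -> Production:
    """Parse one ``pred : cond -> succ`` rule line."""
    raw = line
    head, arrow, succ_src = line.partition("->")
    if not arrow:
        raise GrammarError(f"missing '->' in rule: {raw!r}")
    pred_src, colon, cond_src = head.partition(":")
    cond_src = cond_src.strip() if colon else "1"
    if not cond_src:
        cond_src = "1"
    m = re.match(r"\s*([A-Za-z])\s*(?:\(([^()]*)\))?\s*$", pred_src)
    if not m:
        raise GrammarError(f"bad predecessor in rule: {raw!r}")
    letter = m.group(1)
    formals = tuple(t.strip() for t in m.group(2).split(",")) if m.group(2) else ()
    for f in formals:
        if not _SAFE_NAME.match(f):
            raise GrammarError(f"bad formal parameter {f!r} in rule: {raw!r}")
    allowed = set(formals) | {"r", "choice", "and", "or"}
    cond = _compile_expr(cond_src, allowed, f"condition of {raw!r}")

    succ = []
    pos = 0
    text = succ_src.strip()
    while pos < len(text):
        tok = _SUCC_TOKEN.match(text, pos)
        if not tok or tok.end() == pos:
            raise GrammarError(f"cannot parse successor at {text[pos:]!r} in {raw!r}")
        pos = tok.end()
        if tok.group(1):
            s_letter, args = tok.group(1), tok.group(3)
        else:
            s_letter = tok.group(4).replace("−", "-")
            args = tok.group(6)
        codes = ([_compile_expr(a, allowed, f"successor of {raw!r}")
                  for a in _split_args(args)] if args else [])
        if s_letter in ARITY and len(codes) != ARITY[s_letter]:
            raise GrammarError(
                f"successor symbol {s_letter} expects {ARITY[s_letter]} params "
                f"in rule: {raw!r}")
        succ.append((s_letter, codes))
    return Production(letter=letter, formals=formals, cond_src=cond_src,
                      cond=cond, succ=succ, raw=raw)


def parse_grammar(text: str) -> list[Production]:
    rules = []
    for line in text.splitlines():
        # '#' is the leaf-angle operator, so comments are full-line only
        line = line.strip()
        if line and not line.startswith("#"):
            rules.append(parse_production(line))
    if not rules:
        raise GrammarError("grammar contains no rules")
    return rules


def load_grammar(variety: str) -> list[Production]:
    """Load one of the packaged default grammars ('ordinary' or 'cherry')."""
    ref = resources.files("tomastem") / "grammars" / f"{variety}.lsys"
    return parse_grammar(ref.read_text())


# ---------------------------------------------------------------------------
# rewriting

def make_axiom(choice: ChoiceString | tuple, variety: str = "ordinary") -> LString:
    """Axiom: a young main stem A(i=0, j=0) that will consume the choice codes."""
    if not isinstance(choice, ChoiceString):
        choice = ChoiceString(tuple(choice))
    return LString([SymbolInstance("A", (0, 0))], choice=choice)


def match(prod: Production, sym: SymbolInstance, choice=None) -> bool:
    """Letter, arity and condition must all hold."""
    return prod.matches(sym, choice)


def _age_in_place(sym: SymbolInstance, maturity: dict) -> SymbolInstance:
    """Default behavior for organ symbols with no holding production."""
    if sym.letter in ORGAN_LETTERS and sym.params:
        age = sym.params[-1]
        if age == R:
            return sym
        new_age = age + 1
        if new_age >= maturity.get(sym.letter, 10 ** 9):
            new_age = R
        return SymbolInstance(sym.letter, sym.params[:-1] + (new_age,))
    return sym


def step(s: LString, rules: list[Production], seed: int | None = None,
         maturity: dict | None = None) -> LString:
    """One parallel rewrite.

    Each symbol with exactly one holding production is replaced by its
    successor; two holding productions raise ``GrammarError``; organ
    symbols with none age in place (age+1 until maturity, then r); brackets
    and operators pass through unchanged.  ``seed`` is accepted for
    interface symmetry -- the rewrite itself is deterministic.
    """
    maturity = maturity or DEFAULT_MATURITY
    out: list[SymbolInstance] = []
    for sym in s.symbols:
        if sym.letter in BRACKETS or sym.letter in OPERATOR_LETTERS:
            out.append(sym)
            continue
        holding = [p for p in rules if p.matches(sym, s.choice)]
        if len(holding) > 1:
            raise GrammarError(
                f"ambiguous: {len(holding)} productions hold for {sym}: "
                + "; ".join(p.raw for p in holding))
        if holding:
            out.extend(holding[0].expand(sym, s.choice))
        else:
            out.append(_age_in_place(sym, maturity))
    return LString(out, choice=s.choice)


def grow(axiom: LString, n_stages: int, rules: list[Production],
         seed: int | None = None, maturity: dict | None = None) -> list[LString]:
    """The full growth sequence: [axiom, stage1, ..., stage n]."""
    if n_stages < 0:
        raise ValueError("n_stages must be >= 0")
    stages = [axiom]
    for _ in range(n_stages):
        stages.append(step(stages[-1], rules, seed=seed, maturity=maturity))
    return stages


def branch_types(s: LString) -> list[int]:
    """Lateral-branch form codes in bottom-to-top order.

    Each depth-1 bracket group hanging off the main stem is one lateral
    branch; its code is read from the first form-identifying symbol inside
    (C/S -> 1, f -> 2, h -> 3, D/Y -> their type parameter, B -> its type
    parameter).
    """
    codes, depth, current = [], 0, None
    for sym in s.symbols:
        if sym.letter == "[":
            depth += 1
            if depth == 1:
                current = None
            continue
        if sym.letter == "]":
            if depth == 1 and current is not None:
                codes.append(current)
            depth -= 1
            continue
        if depth >= 1 and current is None:
            if sym.letter in _BRANCH_CODE:
                current = _BRANCH_CODE[sym.letter]
            elif sym.letter in {"B", "D", "Y"}:
                current = int(sym.params[0])
    return codes
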