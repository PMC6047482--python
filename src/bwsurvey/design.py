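"""Blocked assignment of items to ranking sets.

Builds the survey's incomplete block structure — here 21 harms split into
12 sets of 7 with each harm in exactly 4 sets — and maps respondents to a
set by birth month. Because the replication index λ = r(k−1)/(I−1) need not
be integral, exact pairwise balance can be impossible; the generator
searches for *near*-balance: minimum variance of pairwise co-occurrence
counts, via randomized greedy construction plus pairwise-swap hill-climbing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import BalanceSearchError, InfeasibleDesignError, ValidationError


@dataclass(frozen=True)
class BlockDesign:
    """An equal-replication assignment of items to equal-size blocks.

    ``items`` fixes the presentation order (normally catalog order); blocks
    are stored with their members in that order.
    """

    items: tuple
    blocks: tuple

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValidationError("a design needs at least one block")
        sizes = {len(b) for b in self.blocks}
        if len(sizes) != 1:
            raise ValidationError(f"blocks have unequal sizes: {sorted(sizes)}")
        item_set = set(self.items)
        if len(item_set) != len(self.items):
            raise ValidationError("duplicate item in design item list")
        reps: dict = {i: 0 for i in self.items}
        for b in self.blocks:
            if len(set(b)) != len(b):
                raise ValidationError(f"block contains a repeated item: {b}")
            for i in b:
                if i not in item_set:
                    raise ValidationError(f"block item {i!r} not in design items")
                reps[i] += 1
        if len(set(reps.values())) != 1:
            raise ValidationError(f"unequal replication across items: {reps}")

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def block_size(self) -> int:
        return len(self.blocks[0])

    @property
    def replication(self) -> int:
        return self.n_blocks * self.block_size // self.n_items

    def block_items(self, set_id: int) -> tuple:
        """Members of 1-based block ``set_id``."""
        if not 1 <= set_id <= self.n_blocks:
            raise ValidationError(f"set_id {set_id} outside 1–{self.n_blocks}")
        return self.blocks[set_id - 1]


def required_replication(n_items: int, n_blocks: int, block_size: int) -> int:
    """Per-item replication forced by the design parameters.

    Equal frequency requires n_blocks × block_size / n_items to be an
    integer; otherwise the parameters are infeasible.
    """
    if min(n_items, n_blocks, block_size) <= 0:
        raise ValidationError("n_items, n_blocks and block_size must be positive")
    q, rem = divmod(n_blocks * block_size, n_items)
    if rem:
        raise InfeasibleDesignError(
            f"no equal-frequency design: {n_blocks} blocks × {block_size} slots "
            f"/ {n_items} items = {n_blocks * block_size / n_items:.4g} "
            f"(fractional replication)"
        )
    return q


def _convex_int_min(total: int, slots: int, fn) -> int:
    """Min of sum fn(x_i) over nonneg integers with fixed sum, fn convex."""
    if slots == 0:
        return 0
    q, rem = divmod(total, slots)
    return (slots - rem) * fn(q) + rem * fn(q + 1)


def _pair_objective_bound(n_items: int, n_blocks: int, block_size: int) -> int:
    """Lower bound for sum of squared pairwise co-occurrence counts.

    Two valid bounds, take the larger. (a) Convexity over the item pairs
    directly. (b) Σc² = Σc + 2·Σ_pairs C(c,2), and Σ_pairs C(c,2) equals
    Σ_block-pairs C(|B_i ∩ B_j|, 2), whose total Σ|B_i ∩ B_j| is fixed at
    n_items·C(r,2) by the equal replication r — convexity again. Bound (b)
    is what proves exact {1,2} co-occurrence impossible at (21, 12, 7).
    """
    total = n_blocks * block_size * (block_size - 1) // 2
    n_pairs = n_items * (n_items - 1) // 2
    if n_pairs == 0:
        return 0
    naive = _convex_int_min(total, n_pairs, lambda c: c * c)
    r = n_blocks * block_size // n_items
    inter_total = n_items * r * (r - 1) // 2
    n_block_pairs = n_blocks * (n_blocks - 1) // 2
    pair_excess = _convex_int_min(inter_total, n_block_pairs, lambda m: m * (m - 1) // 2)
    return max(naive, total + 2 * pair_excess)


def _initial_incidence(
    n_items: int, n_blocks: int, block_size: int, replication: int, rng
) -> np.ndarray:
    """Random equal-replication incidence matrix (items × blocks)."""
    for _ in range(200):
        quota = np.full(n_items, replication)
        A = np.zeros((n_items, n_blocks), dtype=bool)
        ok = True
        for b in range(n_blocks):
            # largest remaining quota first, random tie-break
            order = np.lexsort((rng.random(n_items), -quota))
            chosen = [i for i in order if quota[i] > 0][:block_size]
            if len(chosen) < block_size:
                ok = False
                break
            A[chosen, b] = True
            quota[chosen] -= 1
        if ok and (quota == 0).all():
            return A
    raise InfeasibleDesignError(
        f"could not construct an equal-replication incidence for "
        f"({n_items}, {n_blocks}, {block_size})"
    )


def _objective(C: np.ndarray) -> int:
    off = C.astype(np.int64).copy()
    np.fill_diagonal(off, 0)
    return int((off * off).sum() // 2)


def _anneal(
    A: np.ndarray,
    rng,
    steps: int,
    bound: int,
    cap: int,
    *,
    t_start: float = 2.5,
    t_end: float = 0.02,
    penalty_weight: int = 3,
) -> tuple[int, int]:
    """In-place simulated annealing on pairwise-swap moves.

    Primary objective is the sum of squared co-occurrence counts; a soft
    penalty on counts above ``cap`` (the ceiling of the mean) breaks ties
    among minimum-variance optima in favour of the tightest spread.
    Returns ``(objective, penalty)``.
    """
    n_items, n_blocks = A.shape
    C = A.astype(np.int64) @ A.T.astype(np.int64)
    off = C.copy()
    np.fill_diagonal(off, 0)
    obj = int((off * off).sum() // 2)
    pen = penalty_weight * int(np.maximum(off - cap, 0).sum() // 2)
    temps = t_start * (t_end / t_start) ** (np.arange(max(1, steps)) / max(1, steps))

    def pen_change(c: np.ndarray, d: int) -> np.ndarray:
        return penalty_weight * (
            np.maximum(c + d - cap, 0) - np.maximum(c - cap, 0)
        )

    for step in range(steps):
        if obj <= bound and pen == 0:
            break
        a = int(rng.integers(n_blocks))
        b = int(rng.integers(n_blocks))
        if a == b:
            continue
        col_a, col_b = A[:, a], A[:, b]
        only_a = np.flatnonzero(col_a & ~col_b)
        only_b = np.flatnonzero(col_b & ~col_a)
        if only_a.size == 0 or only_b.size == 0:
            continue
        i = only_a[rng.integers(only_a.size)]
        j = only_b[rng.integers(only_b.size)]
        ax = only_a[only_a != i]  # members only the swap partners change against
        bx = only_b[only_b != j]
        d_obj = (
            (-2 * C[i, ax] + 1).sum()
            + (2 * C[j, ax] + 1).sum()
            + (-2 * C[j, bx] + 1).sum()
            + (2 * C[i, bx] + 1).sum()
        )
        d_pen = (
            pen_change(C[i, ax], -1).sum()
            + pen_change(C[j, ax], 1).sum()
            + pen_change(C[j, bx], -1).sum()
            + pen_change(C[i, bx], 1).sum()
        )
        delta = d_obj + d_pen
        if delta <= 0 or rng.random() < np.exp(-delta / temps[step]):
            A[i, a], A[i, b] = False, True
            A[j, b], A[j, a] = False, True
            C[i, ax] -= 1
            C[ax, i] -= 1
            C[j, ax] += 1
            C[ax, j] += 1
            C[j, bx] -= 1
            C[bx, j] -= 1
            C[i, bx] += 1
            C[bx, i] += 1
            obj += int(d_obj)
            pen += int(d_pen)
    return obj, pen


def generate_design(
    n_items: int,
    n_blocks: int,
    block_size: int,
    seed: int,
    item_ids: Optional[Sequence[str]] = None,
    *,
    max_restarts: int = 8,
    max_steps: int = 60_000,
) -> BlockDesign:
    """Search for a near-balanced equal-replication design, reproducibly.

    Same seed → identical block lists. A design is accepted once it attains
    the provable lower bound on co-occurrence variance; raises
    :class:`~bwsurvey.errors.BalanceSearchError` (carrying the best balance
    score found) if no restart reaches it within the step budget.
    """
    replication = required_replication(n_items, n_blocks, block_size)
    if block_size > n_items:
        raise InfeasibleDesignError(
            f"block_size {block_size} exceeds n_items {n_items}"
        )
    if item_ids is None:
        item_ids = [f"item{i + 1:02d}" for i in range(n_items)]
    else:
        item_ids = list(item_ids)
        if len(item_ids) != n_items:
            raise ValidationError(
                f"item_ids has {len(item_ids)} entries, expected {n_items}"
            )
    rng = np.random.default_rng(seed)
    bound = _pair_objective_bound(n_items, n_blocks, block_size)
    n_pairs = n_items * (n_items - 1) // 2
    mean_cooc = n_blocks * block_size * (block_size - 1) / 2 / max(1, n_pairs)
    cap = max(1, int(np.ceil(mean_cooc)))

    best_A: Optional[np.ndarray] = None
    best_key = (np.inf, np.inf)
    for _ in range(max(1, max_restarts)):
        A = _initial_incidence(n_items, n_blocks, block_size, replication, rng)
        obj, pen = _anneal(A, rng, max_steps, bound, cap)
        if (obj, pen) < best_key:
            best_key, best_A = (obj, pen), A
        if best_key[0] <= bound and best_key[1] == 0:
            break

    assert best_A is not None
    best_obj = best_key[0]
    C = best_A.astype(np.int64) @ best_A.T.astype(np.int64)
    off = C[~np.eye(n_items, dtype=bool)]
    spread = int(off.max() - off.min()) if n_items > 1 else 0
    if best_obj > bound:
        raise BalanceSearchError(
            f"design search exhausted ({max_restarts} restarts × {max_steps} "
            f"steps): best pair-count objective {int(best_obj)} > bound {bound} "
            f"(co-occurrence spread {spread})",
            best_objective=int(best_obj),
            best_spread=spread,
        )
    blocks = tuple(
        tuple(item_ids[i] for i in np.flatnonzero(best_A[:, b]))
        for b in range(n_blocks)
    )
    return BlockDesign(items=tuple(item_ids), blocks=blocks)


def cooccurrence_matrix(design: BlockDesign) -> pd.DataFrame:
    """Symmetric block co-membership counts; diagonal equals replication."""
    index = {item: i for i, item in enumerate(design.items)}
    A = np.zeros((design.n_items, design.n_blocks), dtype=np.int64)
    for b, block in enumerate(design.blocks):
        for item in block:
            A[index[item], b] = 1
    C = A @ A.T
    return pd.DataFrame(C, index=list(design.items), columns=list(design.items))


def assign_set(birth_month: int, n_blocks: int) -> int:
    """Deterministic month → set mapping: month m → ((m−1) mod n_blocks) + 1."""
    if not 1 <= birth_month <= 12:
        raise ValidationError(f"birth_month {birth_month} outside 1–12")
    if n_blocks <= 0:
        raise ValidationError("n_blocks must be positive")
    return (birth_month - 1) % n_blocks + 1


def save_design(design: BlockDesign, path) -> None:
    rows = [
        {"set_id": set_id, "item_id": item}
        for set_id, block in enumerate(design.blocks, start=1)
        for item in block
    ]
    pd.DataFrame(rows, columns=["set_id", "item_id"]).to_csv(
        Path(path), index=False, lineterminator="\n"
    )


def load_design(path, item_order: Optional[Sequence[str]] = None) -> BlockDesign:
    """Load a ``set_id,item_id`` CSV back into a validated design.

    ``item_order`` fixes the item ordering (e.g. catalog order); by default
    first appearance order in the file is used.
    """
    df = pd.read_csv(path, dtype={"set_id": int, "item_id": str}, comment="#")
    if list(df.columns) != ["set_id", "item_id"]:
        raise ValidationError(
            f"{path}: design file must have columns set_id,item_id"
        )
    if item_order is None:
        seen: dict = {}
        for item in df["item_id"]:
            seen.setdefault(item, None)
        item_order = list(seen)
    order_index = {item: i for i, item in enumerate(item_order)}
    set_ids = sorted(df["set_id"].unique())
    if set_ids != list(range(1, len(set_ids) + 1)):
        raise ValidationError(f"{path}: set_id values must be 1..n_blocks, got {set_ids}")
    blocks = []
    for set_id in set_ids:
        members = list(df.loc[df["set_id"] == set_id, "item_id"])
        unknown = [m for m in members if m not in order_index]
        if unknown:
            raise ValidationError(f"{path}: items {unknown} not in item order")
        blocks.append(tuple(sorted(members, key=order_index.__getitem__)))
    return BlockDesign(items=tuple(item_order), blocks=tuple(blocks))
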