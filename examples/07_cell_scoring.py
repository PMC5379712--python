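"""Cell-scoring rules: fiber co-localization, replication timing, mitoses.

All three scorers consume already-scored tabular records.  A fiber counts
as co-localization positive when at least half of its tagged CENP-A foci
carry CENP-C; replication timing pools EdU+/CENP-B+ counts over cells of a
phase; mitotic cells fall into four exclusive categories.
"""

from nucleodyn import (
    CellCycleCount,
    FiberRecord,
    MitoticCell,
    classify_mitoses,
    replication_fraction,
    score_fibers,
)

# 18 fibers, 12 of them with >= 50% co-localized foci
fibers = [FiberRecord(f"f{i}", 10, 8 if i < 12 else 3) for i in range(18)]
s = score_fibers(fibers)
print(f"fibers: {s.n_positive}/{s.n_total} co-localization positive ({s.percent}%)")

counts = [
    CellCycleCount("c1", "lateS", 100, 37),
    CellCycleCount("c2", "midS", 40, 10),
    CellCycleCount("c3", "midS", 10, 5),
]
print(f"late-S replication: {replication_fraction(counts, 'lateS'):.0f}% "
      f"of CENP-B foci are EdU+")
print(f"mid-S replication (pooled over 2 cells): "
      f"{replication_fraction(counts, 'midS'):.0f}%  (15/50, not the 32.5% "
      f"a mean of per-cell ratios would give)")

cells = ([MitoticCell(f"l{i}", True, False) for i in range(24)]
         + [MitoticCell(f"m{i}", False, True) for i in range(4)]
         + [MitoticCell(f"b{i}", True, True) for i in range(3)]
         + [MitoticCell(f"n{i}", False, False) for i in range(69)])
out = classify_mitoses(cells)
for cat, v in out.items():
    print(f"  {cat:>20s}: {v['count']:3d} cells ({v['percent']:.0f}%)")
print("Categories partition the population, so the percentages sum to 100.")
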