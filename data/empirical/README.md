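# Empirical connectome (not redistributed)

Place the study's 80-region structural connectome here as plain-text
matrices to enable the connectome-dependent sleep-statistics checks:

- `weights.txt` — dense 80 x 80 fiber-count matrix (whitespace-delimited)
- `lengths.txt` — dense 80 x 80 fiber-length matrix, mm
- `labels.txt`  — one region name per line
- `coords.txt`  — 80 x 3 centroid coordinates, mm (column 2 = y =
  anterior-posterior axis, larger = anterior)

The loader symmetrizes, zeroes the diagonal and max-normalizes the weight
matrix, and converts lengths to delays with the global signal speed
(default 20 m/s).
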