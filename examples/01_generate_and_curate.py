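"""Generate a synthetic solubility library and run it through curation.

The generator decorates ring scaffolds with common substituents and assigns
each molecule a noiseless log(S) from a linear model over structural counts,
plus Gaussian measurement noise (sigma = 0.17 emulates a low-variance
"tight" assay regime).  Curation re-standardizes, deduplicates and filters.
"""

from solqspr.curation import curate
from solqspr.synthetic import SyntheticSpec, generate_library

lib = generate_library(SyntheticSpec(n_molecules=100, seed=1, noise_sigma=0.17))
print(f"generated {len(lib)} molecules, e.g. {lib.records[0].smiles}")
print(f"noiseless log(S) range: {lib.truth.min():.2f} .. {lib.truth.max():.2f}")
print(f"observed-vs-truth SD:   {(lib.noisy - lib.truth).std():.3f}  (drawn noise)")

records, report = curate(
    (r.id, r.smiles, r.logS, r.source) for r in lib.records
)
print(f"curation retained {report.retained}/{report.n_input} "
      f"({report.deduplicated} duplicates removed)")
# every generated molecule passes the size/flexibility filters by construction
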