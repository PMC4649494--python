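"""Inspect every similarity layer the heterogeneous network is built from.

Prints, for one synthetic condition, the mean within-module and
between-module similarity of each source: disease semantic similarity (SS),
lincRNA expression similarity (ES), functional similarity (FS), the two
Gaussian interaction-profile kernels (KD, KL) and the integrated matrices
(DS, LS). A well-formed planted condition shows higher within-module values
in every informative source.
"""

import numpy as np

from katzlda import (FixtureSpec, expression_similarity, gaussian_kernel_matrix,
                     generate_inputs, make_model)
from katzlda.profiles import functional_similarity_from_frame
from katzlda.semantic import corpus_from_ontology, semantic_similarity_matrix

bundle = generate_inputs(FixtureSpec(seed=1))
net = bundle.network


def contrast(matrix, ids, blocks):
    index = {x: i for i, x in enumerate(ids)}
    rows = [index[x] for x in ids]
    same = blocks[:, None] == blocks[None, :]
    off = ~np.eye(len(ids), dtype=bool)
    values = matrix[np.ix_(rows, rows)]
    return values[same & off].mean(), values[~same].mean()


corpus, annotated = corpus_from_ontology(bundle.ontology_edges,
                                         bundle.disease_mapping,
                                         list(net.disease_ids))
ss = semantic_similarity_matrix(corpus, annotated)
dis_blocks = np.array([(int(d[1:]) - 1) % 4 for d in annotated])
within, between = contrast(ss.values, annotated, dis_blocks)
print(f"SS  (semantic, {len(annotated)} annotated diseases): "
      f"within {within:.3f} vs between {between:.3f}")

es, we = expression_similarity(bundle.expression, net.lncrna_ids)
fs, wf = functional_similarity_from_frame(bundle.functional, net.lncrna_ids)
lnc_blocks = np.array([(int(l[1:]) - 1) % 4 for l in net.lncrna_ids])
for name, matrix in (("ES", es), ("FS", fs)):
    within, between = contrast(matrix.values, net.lncrna_ids, lnc_blocks)
    print(f"{name}  ({matrix.role}): within {within:.3f} vs between {between:.3f}")

for side, label in (("disease", "KD"), ("lncrna", "KL")):
    kernel = gaussian_kernel_matrix(net, side)
    ids = net.disease_ids if side == "disease" else net.lncrna_ids
    blocks = np.array([(int(x[1:]) - 1) % 4 for x in ids])
    within, between = contrast(kernel.values, ids, blocks)
    print(f"{label}  (Gaussian kernel): within {within:.3f} vs between {between:.3f}")

model = make_model(net, ontology=(bundle.ontology_edges, bundle.disease_mapping),
                   expression_profiles=bundle.expression,
                   functional_frame=bundle.functional)
ls, ds = model.similarities(net)
within, between = contrast(ds.values, net.disease_ids,
                           np.array([(int(d[1:]) - 1) % 4 for d in net.disease_ids]))
print(f"DS  (integrated disease): within {within:.3f} vs between {between:.3f}")
within, between = contrast(ls.values, net.lncrna_ids, lnc_blocks)
print(f"LS  (integrated lncRNA): within {within:.3f} vs between {between:.3f}")
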