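"""Build a small knowledge graph from an edge list and summarise it.

The graph links drugs to their adverse reactions (ADRs), clinical
indications and protein targets. Only drugs with at least one edge of each
type are kept, because the predictor needs all three kinds of evidence.
"""

import io
import json

from adrkg import filter_complete_drugs, load_graph, summarize_graph

EDGES = """\
drug_id\tnode_id\tnode_type
CID2244\tC0004093\tadr
CID2244\tC0030193\tindication
CID2244\tP23219\ttarget
CID3672\tC0004093\tadr
CID3672\tC0018681\tindication
CID3672\tP23219\ttarget
CID5090\tC0027497\tadr
CID5090\tP35354\ttarget
"""

g = load_graph(io.StringIO(EDGES))
print("raw graph:      ", g)
g = filter_complete_drugs(g)
print("filtered graph: ", g)  # CID5090 dropped: it has no indication edge

summary = summarize_graph(g)
print(json.dumps(summary, indent=2))
# median_causes_per_adr / median_adrs_per_drug describe how interconnected
# the drug-ADR layer is; prevalence is the fraction of drugs causing an ADR.
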