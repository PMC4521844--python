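"""smydkit: classification framework for the Smyd gene family.

Homology-filtered sequence collection, SET-MYND core extraction,
distance-based phylogeny with bootstrap, degenerate MYND Zn-finger
detection, domain-architecture assembly and combined tree+architecture
class assignment, plus a synthetic-family generator with full ground truth.
"""

__version__ = "0.1.0"

from .classification import (
    AnchorSet, ClassAssignment, ClassLabel, assign_classes, assign_subgroups,
    suggest_ortholog,
)
from .core_alignment import ColumnPolicy, CoreRegion, apply_column_policy, extract_core
from .domain_architecture import (
    AcidicTract, Architecture, DomainAnnotation, SmydCore, architecture_class,
    assemble_architecture, detect_acidic_tract, detect_tpr_heuristic,
)
from .homology_filter import (
    CandidateVerdict, FilterConfig, filter_by_evalue_and_continuity,
    reciprocal_best,
)
from .phylogeny import (
    BootstrapConfig, DistanceMatrix, DistanceModel, bipartitions,
    bootstrap_support, distance_matrix, neighbor_joining, pairwise_distance,
    robinson_foulds,
)
from .pipeline import PipelineConfig, run_pipeline, species_class_counts
from .seq_io import (
    Alignment, BlastHitRow, ProteinSeq, read_alignment, read_blast_tab,
    read_fasta, read_newick, write_fasta, write_newick,
)
from .synthetic_data import SynthConfig, evolve_sequences, generate_family, simulate_tree
from .zinc_finger import (
    RelaxPolicy, ZnFingerHit, ZnPattern, best_finger, categorize,
    enumerate_candidate_fingers, finger_report,
)
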