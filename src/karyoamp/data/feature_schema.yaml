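version: 1
n_features: 237
columns:
- modal_number
- modal_range_low
- modal_range_high
- modal_range_mid
- modal_range_width
- percent_polyploidy
- ploidy_near_haploid
- ploidy_near_diploid
- ploidy_near_triploid
- ploidy_near_tetraploid
- ploidy_hyperploid
- ploidy_unknown
- sex_n_x
- sex_n_y
- sex_has_y
- marker_min
- marker_max
- marker_mid
- marker_present
- dmin_min
- dmin_max
- dmin_mid
- dmin_present
- hsr_count
- hsr_present
- sv_total
- n_add
- n_del
- n_der
- n_dup
- n_t
- n_iso
- unparsed_tokens
- total_gains
- total_losses
- n_chrom_gained
- n_chrom_lost
- n_derivative_chroms
- n_translocation_chroms
- aberration_burden
- ploidy_index
- sex_total
- has_modal_range
- composite_count
- detail_score
- gain_chr1
- gain_chr2
- gain_chr3
- gain_chr4
- gain_chr5
- gain_chr6
- gain_chr7
- gain_chr8
- gain_chr9
- gain_chr10
- gain_chr11
- gain_chr12
- gain_chr13
- gain_chr14
- gain_chr15
- gain_chr16
- gain_chr17
- gain_chr18
- gain_chr19
- gain_chr20
- gain_chr21
- gain_chr22
- gain_chrX
- gain_chrY
- loss_chr1
- loss_chr2
- loss_chr3
- loss_chr4
- loss_chr5
- loss_chr6
- loss_chr7
- loss_chr8
- loss_chr9
- loss_chr10
- loss_chr11
- loss_chr12
- loss_chr13
- loss_chr14
- loss_chr15
- loss_chr16
- loss_chr17
- loss_chr18
- loss_chr19
- loss_chr20
- loss_chr21
- loss_chr22
- loss_chrX
- loss_chrY
- der_chr1
- der_chr2
- der_chr3
- der_chr4
- der_chr5
- der_chr6
- der_chr7
- der_chr8
- der_chr9
- der_chr10
- der_chr11
- der_chr12
- der_chr13
- der_chr14
- der_chr15
- der_chr16
- der_chr17
- der_chr18
- der_chr19
- der_chr20
- der_chr21
- der_chr22
- der_chrX
- der_chrY
- trans_chr1
- trans_chr2
- trans_chr3
- trans_chr4
- trans_chr5
- trans_chr6
- trans_chr7
- trans_chr8
- trans_chr9
- trans_chr10
- trans_chr11
- trans_chr12
- trans_chr13
- trans_chr14
- trans_chr15
- trans_chr16
- trans_chr17
- trans_chr18
- trans_chr19
- trans_chr20
- trans_chr21
- trans_chr22
- trans_chrX
- trans_chrY
- add_chr1
- add_chr2
- add_chr3
- add_chr4
- add_chr5
- add_chr6
- add_chr7
- add_chr8
- add_chr9
- add_chr10
- add_chr11
- add_chr12
- add_chr13
- add_chr14
- add_chr15
- add_chr16
- add_chr17
- add_chr18
- add_chr19
- add_chr20
- add_chr21
- add_chr22
- add_chrX
- add_chrY
- del_chr1
- del_chr2
- del_chr3
- del_chr4
- del_chr5
- del_chr6
- del_chr7
- del_chr8
- del_chr9
- del_chr10
- del_chr11
- del_chr12
- del_chr13
- del_chr14
- del_chr15
- del_chr16
- del_chr17
- del_chr18
- del_chr19
- del_chr20
- del_chr21
- del_chr22
- del_chrX
- del_chrY
- dup_chr1
- dup_chr2
- dup_chr3
- dup_chr4
- dup_chr5
- dup_chr6
- dup_chr7
- dup_chr8
- dup_chr9
- dup_chr10
- dup_chr11
- dup_chr12
- dup_chr13
- dup_chr14
- dup_chr15
- dup_chr16
- dup_chr17
- dup_chr18
- dup_chr19
- dup_chr20
- dup_chr21
- dup_chr22
- dup_chrX
- dup_chrY
- iso_chr1
- iso_chr2
- iso_chr3
- iso_chr4
- iso_chr5
- iso_chr6
- iso_chr7
- iso_chr8
- iso_chr9
- iso_chr10
- iso_chr11
- iso_chr12
- iso_chr13
- iso_chr14
- iso_chr15
- iso_chr16
- iso_chr17
- iso_chr18
- iso_chr19
- iso_chr20
- iso_chr21
- iso_chr22
- iso_chrX
- iso_chrY
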