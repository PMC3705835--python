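record_id,age_years,lactate_csf,glucose_csf,glucose_serum,tp_csf,albumin_csf,albumin_serum,beta2m_csf,leukocytes,erythrocytes,fraction_lymphocyte,fraction_monocyte,fraction_granulocyte,malignant_cells_present,it_igg,it_iga,it_igm
patient-A,35,1.2,3.2,5.4,350,180,42000,1.1,2,1,0.7,0.3,0.0,false,0,0,0
patient-B,52,18.0,0.9,4.5,900,500,43000,3.5,450,40,0.05,0.10,0.85,false,0,0,0
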