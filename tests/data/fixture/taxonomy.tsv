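feature_id	taxonomy
ASV0001	d__Bacteria;p__SoilPhylum;c__SoilClass;o__SoilOrder;f__SoilFamily00;g__Soil_g00
ASV0002	d__Bacteria;p__SoilPhylum;c__SoilClass;o__SoilOrder;f__SoilFamily00;g__Soil_g01
ASV0003	d__Bacteria;p__SoilPhylum;c__SoilClass;o__SoilOrder;f__SoilFamily00;g__Soil_g02
ASV0004	d__Bacteria;p__SoilPhylum;c__SoilClass;o__SoilOrder;f__SoilFamily01;g__Soil_g03
ASV0005	d__Bacteria;p__SoilPhylum;c__SoilClass;o__SoilOrder;f__SoilFamily01;g__Soil_g04
ASV0006	d__Bacteria;p__SoilPhylum;c__SoilClass;o__SoilOrder;f__SoilFamily01;g__Soil_g04
ASV0007	d__Bacteria;p__SoilPhylum;c__SoilClass;o__SoilOrder;f__SoilFamily02;g__Soil_g06
ASV0008	d__Bacteria;p__SoilPhylum;c__SoilClass;o__SoilOrder;f__SoilFamily07;g__
ASV0009	d__Bacteria;p__SoilPhylum;c__SoilClass;o__SoilOrder;f__SoilFamily02;g__Soil_g08
ASV0010	d__Bacteria;p__SoilPhylum;c__SoilClass;o__SoilOrder;f__SoilFamily03;g__Soil_g09
ASV0011	d__Bacteria;p__SoilPhylum;c__SoilClass;o__SoilOrder;f__SoilFamily03;g__Soil_g10
ASV0012	d__Bacteria;p__SoilPhylum;c__SoilClass;o__SoilOrder;f__SoilFamily03;g__Soil_g10
ASV0013	d__Bacteria;p__HumanPhylum;c__HumanClass;o__HumanOrder;f__Staphylococcaceae;g__Staphylococcus
ASV0014	d__Bacteria;p__HumanPhylum;c__HumanClass;o__HumanOrder;f__Streptococcaceae;g__Streptococcus
ASV0015	d__Bacteria;p__HumanPhylum;c__HumanClass;o__HumanOrder;f__Propionibacteriaceae;g__Cutibacterium
ASV0016	d__Bacteria;p__HumanPhylum;c__HumanClass;o__HumanOrder;f__Corynebacteriaceae;g__Corynebacterium
ASV0017	d__Bacteria;p__HumanPhylum;c__HumanClass;o__HumanOrder;f__Enterobacteriaceae;g__Escherichia
ASV0018	d__Bacteria;p__HumanPhylum;c__HumanClass;o__HumanOrder;f__Enterobacteriaceae;g__Escherichia
ASV0019	d__Bacteria;p__HumanPhylum;c__HumanClass;o__HumanOrder;f__HumanFamily02;g__Human_g06
ASV0020	d__Bacteria;p__HumanPhylum;c__HumanClass;o__HumanOrder;f__HumanFamily07;g__
ASV0021	d__Bacteria;p__HumanPhylum;c__HumanClass;o__HumanOrder;f__HumanFamily02;g__Human_g08
ASV0022	d__Bacteria;p__HumanPhylum;c__HumanClass;o__HumanOrder;f__HumanFamily03;g__Human_g09
ASV0023	d__Bacteria;p__OutdoorPhylum;c__OutdoorClass;o__OutdoorOrder;f__OutdoorFamily00;g__Outdoor_g00
ASV0024	d__Bacteria;p__OutdoorPhylum;c__OutdoorClass;o__OutdoorOrder;f__OutdoorFamily00;g__Outdoor_g01
ASV0025	d__Bacteria;p__OutdoorPhylum;c__OutdoorClass;o__OutdoorOrder;f__OutdoorFamily00;g__Outdoor_g02
ASV0026	d__Bacteria;p__OutdoorPhylum;c__OutdoorClass;o__OutdoorOrder;f__OutdoorFamily01;g__Outdoor_g03
ASV0027	d__Bacteria;p__OutdoorPhylum;c__OutdoorClass;o__OutdoorOrder;f__OutdoorFamily01;g__Outdoor_g04
ASV0028	d__Bacteria;p__OutdoorPhylum;c__OutdoorClass;o__OutdoorOrder;f__OutdoorFamily01;g__Outdoor_g04
ASV0029	d__Bacteria;p__OutdoorPhylum;c__OutdoorClass;o__OutdoorOrder;f__OutdoorFamily02;g__Outdoor_g06
ASV0030	d__Bacteria;p__OutdoorPhylum;c__OutdoorClass;o__OutdoorOrder;f__OutdoorFamily07;g__
ASV0031	d__Bacteria;p__OutdoorPhylum;c__OutdoorClass;o__OutdoorOrder;f__OutdoorFamily02;g__Outdoor_g08
ASV0032	d__Bacteria;p__HomePhylum;c__HomeClass;o__HomeOrder;f__HomeFamily00;g__Home_g00
ASV0033	d__Bacteria;p__HomePhylum;c__HomeClass;o__HomeOrder;f__HomeFamily00;g__Home_g01
ASV0034	d__Bacteria;p__HomePhylum;c__HomeClass;o__HomeOrder;f__HomeFamily00;g__Home_g02
ASV0035	d__Bacteria;p__HomePhylum;c__HomeClass;o__HomeOrder;f__HomeFamily01;g__Home_g03
ASV0036	d__Bacteria;p__HomePhylum;c__HomeClass;o__HomeOrder;f__HomeFamily01;g__Home_g04
ASV0037	d__Bacteria;p__HomePhylum;c__HomeClass;o__HomeOrder;f__HomeFamily01;g__Home_g04
ASV0038	d__Bacteria;p__HomePhylum;c__HomeClass;o__HomeOrder;f__HomeFamily02;g__Home_g06
ASV0039	d__Bacteria;p__HomePhylum;c__HomeClass;o__HomeOrder;f__HomeFamily07;g__
ASV0040	d__Bacteria;p__HomePhylum;c__HomeClass;o__HomeOrder;f__HomeFamily02;g__Home_g08
ASV0041	d__Bacteria;p__HomePhylum;c__HomeClass;o__HomeOrder;f__HomeFamily03;g__Home_g09
ASV0042	d__Bacteria;p__HomePhylum;c__HomeClass;o__HomeOrder;f__HomeFamily03;g__Home_g10
ASV0043	d__Bacteria;p__HomePhylum;c__HomeClass;o__HomeOrder;f__HomeFamily03;g__Home_g10
ASV0044	d__Bacteria;p__HomePhylum;c__HomeClass;o__ContamOrder;f__ContamFamily;g__Contam_g00
ASV0045	d__Bacteria;p__HomePhylum;c__HomeClass;o__ContamOrder;f__ContamFamily;g__Contam_g01
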