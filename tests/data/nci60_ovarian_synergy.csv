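drug1,drug2,cell_line,score
Erlotinib,Dasatinib,IGROV1,34.44
Gefitinib,Dasatinib,IGROV1,23.22
Vandetanib,Dasatinib,IGROV1,18.44
Dasatinib,Tamoxifen,IGROV1,16.78
Lapatinib,Sirolimus,IGROV1,14.00
Vandetanib,Everolimus,IGROV1,13.56
Celecoxib,Dasatinib,IGROV1,13.11
Lapatinib,Everolimus,IGROV1,12.44
Sirolimus,Tamoxifen,IGROV1,11.67
Lapatinib,Dasatinib,IGROV1,11.00
Gefitinib,Everolimus,IGROV1,10.78
Dasatinib,Imatinib,IGROV1,10.56
Celecoxib,Vandetanib,IGROV1,9.11
Sirolimus,Vandetanib,IGROV1,8.78
Erlotinib,Tamoxifen,IGROV1,8.33
Dasatinib,Tamoxifen,OVCAR-3,11.33
Sirolimus,Everolimus,OVCAR-3,9.56
Celecoxib,Dasatinib,OVCAR-3,9.44
Thalidomide,Dasatinib,OVCAR-3,8.89
Sirolimus,Gefitinib,OVCAR-4,10.56
Gefitinib,Everolimus,OVCAR-4,9.44
Lapatinib,Sirolimus,OVCAR-4,9.44
Vandetanib,Tamoxifen,OVCAR-5,9.33
Dasatinib,Tamoxifen,SK-OV-3,14.78
Everolimus,Tamoxifen,SK-OV-3,11.78
Lapatinib,Dasatinib,SK-OV-3,10.11
Celecoxib,Dasatinib,SK-OV-3,9.56
Gefitinib,Dasatinib,SK-OV-3,9.11
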