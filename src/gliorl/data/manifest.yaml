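# Default radiomics feature manifest: seven standard pyradiomics-style
# categories totalling 105 features (14 shape, 18 first-order, 24 GLCM,
# 13 GLDM, 16 GLRLM, 15 GLSZM, 5 NGTDM).  Names are category-prefixed to
# keep the namespace unique across categories.
version: "1.0"
categories:
  shape:
    - shape_Elongation
    - shape_Flatness
    - shape_LeastAxisLength
    - shape_MajorAxisLength
    - shape_Maximum2DDiameterColumn
    - shape_Maximum2DDiameterRow
    - shape_Maximum2DDiameterSlice
    - shape_Maximum3DDiameter
    - shape_MeshVolume
    - shape_MinorAxisLength
    - shape_Sphericity
    - shape_SurfaceArea
    - shape_SurfaceVolumeRatio
    - shape_VoxelVolume
  firstorder:
    - firstorder_10Percentile
    - firstorder_90Percentile
    - firstorder_Energy
    - firstorder_Entropy
    - firstorder_InterquartileRange
    - firstorder_Kurtosis
    - firstorder_Maximum
    - firstorder_Mean
    - firstorder_MeanAbsoluteDeviation
    - firstorder_Median
    - firstorder_Minimum
    - firstorder_Range
    - firstorder_RobustMeanAbsoluteDeviation
    - firstorder_RootMeanSquared
    - firstorder_Skewness
    - firstorder_TotalEnergy
    - firstorder_Uniformity
    - firstorder_Variance
  glcm:
    - glcm_Autocorrelation
    - glcm_ClusterProminence
    - glcm_ClusterShade
    - glcm_ClusterTendency
    - glcm_Contrast
    - glcm_Correlation
    - glcm_DifferenceAverage
    - glcm_DifferenceEntropy
    - glcm_DifferenceVariance
    - glcm_Id
    - glcm_Idm
    - glcm_Idmn
    - glcm_Idn
    - glcm_Imc1
    - glcm_Imc2
    - glcm_InverseVariance
    - glcm_JointAverage
    - glcm_JointEnergy
    - glcm_JointEntropy
    - glcm_MCC
    - glcm_MaximumProbability
    - glcm_SumAverage
    - glcm_SumEntropy
    - glcm_SumSquares
  gldm:
    - gldm_DependenceEntropy
    - gldm_DependenceNonUniformity
    - gldm_DependenceNonUniformityNormalized
    - gldm_DependenceVariance
    - gldm_GrayLevelNonUniformity
    - gldm_GrayLevelVariance
    - gldm_HighGrayLevelEmphasis
    - gldm_LargeDependenceEmphasis
    - gldm_LargeDependenceHighGrayLevelEmphasis
    - gldm_LowGrayLevelEmphasis
    - gldm_SmallDependenceEmphasis
    - gldm_SmallDependenceHighGrayLevelEmphasis
    - gldm_SmallDependenceLowGrayLevelEmphasis
  glrlm:
    - glrlm_GrayLevelNonUniformity
    - glrlm_GrayLevelNonUniformityNormalized
    - glrlm_GrayLevelVariance
    - glrlm_HighGrayLevelRunEmphasis
    - glrlm_LongRunEmphasis
    - glrlm_LongRunHighGrayLevelEmphasis
    - glrlm_LongRunLowGrayLevelEmphasis
    - glrlm_LowGrayLevelRunEmphasis
    - glrlm_RunEntropy
    - glrlm_RunLengthNonUniformity
    - glrlm_RunLengthNonUniformityNormalized
    - glrlm_RunPercentage
    - glrlm_RunVariance
    - glrlm_ShortRunEmphasis
    - glrlm_ShortRunHighGrayLevelEmphasis
    - glrlm_ShortRunLowGrayLevelEmphasis
  glszm:
    - glszm_GrayLevelNonUniformity
    - glszm_GrayLevelNonUniformityNormalized
    - glszm_GrayLevelVariance
    - glszm_HighGrayLevelZoneEmphasis
    - glszm_LargeAreaEmphasis
    - glszm_LargeAreaHighGrayLevelEmphasis
    - glszm_LargeAreaLowGrayLevelEmphasis
    - glszm_LowGrayLevelZoneEmphasis
    - glszm_SizeZoneNonUniformity
    - glszm_SizeZoneNonUniformityNormalized
    - glszm_SmallAreaEmphasis
    - glszm_SmallAreaHighGrayLevelEmphasis
    - glszm_SmallAreaLowGrayLevelEmphasis
    - glszm_ZoneEntropy
    - glszm_ZonePercentage
  ngtdm:
    - ngtdm_Busyness
    - ngtdm_Coarseness
    - ngtdm_Complexity
    - ngtdm_Contrast
    - ngtdm_Strength
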